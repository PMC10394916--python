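"""Readers/writers for networks, complex collections, and value tables.

File dialects
-------------
* Network: 3-column whitespace/tab-separated edge list ``node node weight``
  with ``#`` comments.  Duplicate edges keep the maximum weight; self-loops
  are dropped with a warning (the node itself is kept).
* Complexes: one complex per line, member identifiers whitespace-separated.
* Value table: versioned JSON with bin edges, values, discount and rewards.
* Predictions: one complex per line, member identifiers followed by a final
  numeric column holding the candidate's value score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

VALUE_TABLE_FORMAT_VERSION = 1

__all__ = [
    "WeightedNetwork",
    "ComplexCollection",
    "NetworkParseError",
    "read_network",
    "write_network",
    "read_complexes",
    "write_complexes",
    "preprocess_complexes",
    "save_value_table",
    "load_value_table",
    "read_predictions",
    "write_predictions",
]


class NetworkParseError(ValueError):
    """Raised for malformed network / complex / table files."""


class WeightedNetwork:
    """Undirected weighted graph of protein nodes.

    Invariants: no self-loops, each unordered pair stored once, all edge
    weights strictly positive.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction ----------------------------------------------------

    def add_node(self, node: str) -> None:
        self._g.add_node(node)

    def add_edge(self, u: str, v: str, weight: float) -> None:
        """Insert an edge; duplicate pairs keep the maximum weight."""
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        w = float(weight)
        if not w > 0:
            raise ValueError(f"non-positive edge weight {weight!r} for {u}-{v}")
        if self._g.has_edge(u, v):
            w = max(w, self._g[u][v]["weight"])
        self._g.add_edge(u, v, weight=w)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "WeightedNetwork":
        net = cls()
        for u, v, w in edges:
            net.add_edge(u, v, w)
        return net

    # -- queries ---------------------------------------------------------

    @property
    def nodes(self) -> set:
        return set(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, node: str) -> bool:
        return self._g.has_node(node)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        if not self._g.has_edge(u, v):
            raise KeyError(f"no edge {u}-{v}")
        return self._g[u][v]["weight"]

    def neighbors(self, node: str) -> set:
        return set(self._g.neighbors(node))

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for u, v, data in self._g.edges(data=True):
            yield u, v, data["weight"]

    def induced_weight(self, members: Iterable[str]) -> float:
        """Sum of edge weights of the subgraph induced by ``members``."""
        mem = set(members)
        total = 0.0
        for u, v, data in self._g.subgraph(mem).edges(data=True):
            total += data["weight"]
        return total

    def is_connected_subset(self, members: Iterable[str]) -> bool:
        mem = set(members)
        if not mem:
            return False
        if len(mem) == 1:
            return True
        sub = self._g.subgraph(mem)
        return nx.is_connected(sub)

    def subgraph_neighbors(self, members: Iterable[str]) -> set:
        """Nodes outside ``members`` sharing at least one edge with it."""
        mem = set(members)
        out: set = set()
        for node in mem:
            out.update(self._g.neighbors(node))
        return out - mem

    def connected_components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self._g)]


@dataclass
class ComplexCollection:
    """Ordered list of named node sets (gold standards or predictions)."""

    complexes: list[tuple[str, frozenset]] = field(default_factory=list)

    @classmethod
    def from_member_sets(
        cls, member_sets: Iterable[Iterable[str]], names: Sequence[str] | None = None
    ) -> "ComplexCollection":
        out = cls()
        for i, members in enumerate(member_sets):
            name = names[i] if names is not None else f"Cx{i + 1}"
            out.append(name, members)
        return out

    def append(self, name: str, members: Iterable[str]) -> None:
        members = frozenset(members)
        if not members:
            raise ValueError(f"complex {name!r} has no members")
        if any(name == n for n, _ in self.complexes):
            raise ValueError(f"duplicate complex name {name!r}")
        self.complexes.append((name, members))

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[tuple[str, frozenset]]:
        return iter(self.complexes)

    def __getitem__(self, idx: int) -> tuple[str, frozenset]:
        return self.complexes[idx]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.complexes]

    @property
    def member_sets(self) -> list[frozenset]:
        return [m for _, m in self.complexes]

    def node_universe(self) -> set:
        out: set = set()
        for _, members in self.complexes:
            out |= members
        return out

    def subset(self, names: Iterable[str]) -> "ComplexCollection":
        """Sub-collection restricted to ``names``, preserving order."""
        wanted = set(names)
        out = ComplexCollection()
        for name, members in self.complexes:
            if name in wanted:
                out.append(name, members)
        return out


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def read_network(path: str | Path) -> WeightedNetwork:
    """Parse a 3-column edge list into a :class:`WeightedNetwork`.

    Duplicate edges keep the maximum weight.  Self-loops are dropped (the
    node is still registered) with a warning.  Malformed lines raise
    :class:`NetworkParseError` naming the line number.
    """
    path = Path(path)
    net = WeightedNetwork()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 'node node weight', got {line!r}"
                )
            u, v, w_str = fields[0], fields[1], fields[2]
            try:
                w = float(w_str)
            except ValueError:
                raise NetworkParseError(
                    f"{path}:{lineno}: non-numeric weight {w_str!r}"
                ) from None
            if not w > 0:
                raise NetworkParseError(
                    f"{path}:{lineno}: non-positive weight {w}"
                )
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                net.add_node(u)
                continue
            net.add_edge(u, v, w)
    return net


def write_network(network: WeightedNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        # isolated nodes are not representable in a 3-column edge list
        pairs = [(min(u, v), max(u, v), w) for u, v, w in network.edges()]
        for u, v, w in sorted(pairs):
            fh.write(f"{u}\t{v}\t{w!r}\n")


# ---------------------------------------------------------------------------
# complexes
# ---------------------------------------------------------------------------

def read_complexes(path: str | Path) -> ComplexCollection:
    """One complex per line; duplicate members within a line collapse."""
    path = Path(path)
    out = ComplexCollection()
    n_seen = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("%s:%d: skipping blank line", path, lineno)
                continue
            members = line.split()
            n_seen += 1
            out.append(f"Cx{n_seen}", members)
    if len(out) == 0:
        raise NetworkParseError(f"{path}: no complexes found")
    return out


def write_complexes(complexes: ComplexCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for _, members in complexes:
            fh.write(" ".join(sorted(members)) + "\n")


def _jaccard(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / len(a | b)


def preprocess_complexes(
    complexes: ComplexCollection,
    network: WeightedNetwork,
    min_size: int = 3,
    jaccard_merge_threshold: float = 0.6,
) -> ComplexCollection:
    """Gold-standard cleanup: restrict to the network, filter, merge.

    Members absent from the network are removed first.  Complexes that then
    have fewer than ``min_size`` members or induce a disconnected subgraph
    are discarded.  Finally, pairs whose Jaccard coefficient exceeds
    ``jaccard_merge_threshold`` are merged (highest-overlap pair first,
    iterated to a fixed point) so that no two survivors overlap by more
    than the threshold.
    """
    if network.n_nodes == 0:
        raise ValueError("network is empty")

    survivors: list[tuple[str, frozenset]] = []
    for name, members in complexes:
        present = frozenset(m for m in members if network.has_node(m))
        if len(present) < min_size:
            logger.warning("dropping complex %s: %d members in network (< %d)",
                           name, len(present), min_size)
            continue
        if not network.is_connected_subset(present):
            logger.warning("dropping complex %s: internally disconnected", name)
            continue
        survivors.append((name, present))

    # iterative merge: always collapse the currently highest-overlap pair
    while True:
        best = None  # (jaccard, i, j)
        for i in range(len(survivors)):
            for j in range(i + 1, len(survivors)):
                jac = _jaccard(survivors[i][1], survivors[j][1])
                if jac > jaccard_merge_threshold:
                    if best is None or jac > best[0]:
                        best = (jac, i, j)
        if best is None:
            break
        _, i, j = best
        name_i, mem_i = survivors[i]
        name_j, mem_j = survivors[j]
        merged = (f"{name_i}+{name_j}", mem_i | mem_j)
        logger.info("merging complexes %s and %s (Jaccard %.3f)",
                    name_i, name_j, best[0])
        survivors = (
            survivors[:i] + [merged] + survivors[i + 1:j] + survivors[j + 1:]
        )

    if not survivors:
        logger.warning("preprocessing removed every complex")
    out = ComplexCollection()
    for name, members in survivors:
        out.append(name, members)
    return out


# ---------------------------------------------------------------------------
# value tables
# ---------------------------------------------------------------------------

def save_value_table(table, path: str | Path) -> None:
    """Serialize a value table to versioned JSON (bit-exact round trip)."""
    path = Path(path)
    payload = {
        "format_version": VALUE_TABLE_FORMAT_VERSION,
        "n_bins": table.n_bins,
        "bin_edges": [float(x) for x in table.bin_edges],
        "values": [float(x) for x in table.values],
        "gamma": table.gamma,
        "rewards": {
            "correct": table.reward_correct,
            "wrong": table.reward_wrong,
            "terminal": table.reward_terminal,
        },
        "trained_on": table.trained_on,
    }
    with path.open("w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_value_table(path: str | Path, expect_n_bins: int | None = None):
    """Load a value table saved by :func:`save_value_table`.

    Version or field mismatches (including an unexpected bin count) raise
    :class:`NetworkParseError`.
    """
    from .state_value import ValueTable

    path = Path(path)
    with path.open() as fh:
        payload = json.load(fh)
    if payload.get("format_version") != VALUE_TABLE_FORMAT_VERSION:
        raise NetworkParseError(
            f"{path}: unsupported value-table version {payload.get('format_version')!r}"
        )
    required = {"n_bins", "bin_edges", "values", "gamma", "rewards"}
    missing = required - payload.keys()
    if missing:
        raise NetworkParseError(f"{path}: missing fields {sorted(missing)}")
    n_bins = int(payload["n_bins"])
    if expect_n_bins is not None and n_bins != expect_n_bins:
        raise NetworkParseError(
            f"{path}: table has {n_bins} bins, expected {expect_n_bins}"
        )
    values = np.asarray(payload["values"], dtype=float)
    if values.shape != (n_bins,):
        raise NetworkParseError(
            f"{path}: {values.size} values for {n_bins} bins"
        )
    edges = np.asarray(payload["bin_edges"], dtype=float)
    if edges.shape != (n_bins + 1,):
        raise NetworkParseError(
            f"{path}: {edges.size} bin edges for {n_bins} bins"
        )
    rewards = payload["rewards"]
    return ValueTable(
        n_bins=n_bins,
        gamma=float(payload["gamma"]),
        reward_correct=float(rewards["correct"]),
        reward_wrong=float(rewards["wrong"]),
        reward_terminal=float(rewards["terminal"]),
        values=values,
        trained_on=payload.get("trained_on"),
    )


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(candidates, path: str | Path) -> None:
    """Members then a final value-score column, one candidate per line."""
    path = Path(path)
    with path.open("w") as fh:
        for cand in candidates:
            fh.write(" ".join(sorted(cand.members)) + f" {cand.score!r}\n")


def read_predictions(path: str | Path) -> list[tuple[frozenset, float]]:
    path = Path(path)
    out: list[tuple[frozenset, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected members plus score column"
                )
            try:
                score = float(fields[-1])
            except ValueError:
                raise NetworkParseError(
                    f"{path}:{lineno}: non-numeric score {fields[-1]!r}"
                ) from None
            out.append((frozenset(fields[:-1]), score))
    return out
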