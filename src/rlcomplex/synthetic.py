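"""Planted-complex network generator and small hand-built fixtures.

The generator plants node-disjoint complexes of configurable topology
(clique, chain, star, ring, or a mixed-density random connected graph),
draws edge weights from a configurable range, optionally sprinkles
low-weight inter-complex noise edges, and returns the ground-truth
collection together with a seeded, stratified train/test split.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .network_io import ComplexCollection, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedNetworkConfig",
    "TrainTestSplit",
    "generate",
    "fig5_preset",
    "fig1_network",
    "TOPOLOGIES",
]

TOPOLOGIES = ("clique", "chain", "star", "ring", "mixed")

# minimum feasible sizes per topology ("mixed" needs a non-tree extra edge)
_MIN_SIZE = {"clique": 3, "chain": 3, "star": 3, "ring": 3, "mixed": 4}


@dataclass
class PlantedNetworkConfig:
    n_complexes: int = 14
    size_range: tuple[int, int] = (3, 6)
    topology_mix: dict[str, float] = field(
        default_factory=lambda: {
            "clique": 0.4, "chain": 0.15, "star": 0.15,
            "ring": 0.15, "mixed": 0.15,
        }
    )
    intra_weight_range: tuple[float, float] = (0.6, 1.0)
    inter_edge_prob: float = 0.0
    inter_weight_range: tuple[float, float] = (0.05, 0.3)
    disconnected: bool = True
    train_fraction: float = 0.5
    rng_seed: int = 0
    # explicit (topology, size) layout overriding the random draws; the
    # listed order becomes the collection (and hence training) order
    layout: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if lo > hi or lo < 3:
            raise ValueError(f"invalid size range {self.size_range}")
        wlo, whi = self.intra_weight_range
        if not (0 < wlo <= whi <= 1):
            raise ValueError(
                f"intra weight range must lie in (0, 1], got {self.intra_weight_range}"
            )
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0 <= self.inter_edge_prob < 1:
            raise ValueError("inter_edge_prob must lie in [0, 1)")
        if self.disconnected:
            self.inter_edge_prob = 0.0
        if self.layout is not None:
            self.layout = tuple((str(t), int(s)) for t, s in self.layout)
            self.n_complexes = len(self.layout)
            for topo, size in self.layout:
                _validate_shape(topo, size)
        if self.n_complexes < 2:
            raise ValueError("need at least two complexes to split")

    def resolved_layout(self, rng: np.random.Generator) -> list[tuple[str, int]]:
        if self.layout is not None:
            return list(self.layout)
        topos = sorted(self.topology_mix)
        probs = np.array([self.topology_mix[t] for t in topos], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("topology_mix proportions must sum to > 0")
        probs = probs / probs.sum()
        lo, hi = self.size_range
        out: list[tuple[str, int]] = []
        for _ in range(self.n_complexes):
            topo = str(rng.choice(topos, p=probs))
            size = int(rng.integers(max(lo, _MIN_SIZE[topo]), hi + 1))
            _validate_shape(topo, size)
            out.append((topo, size))
        return out


def _validate_shape(topo: str, size: int) -> None:
    if topo not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topo!r}")
    if size < _MIN_SIZE[topo]:
        raise ValueError(f"{topo} complex needs >= {_MIN_SIZE[topo]} nodes, got {size}")


@dataclass
class TrainTestSplit:
    train_names: list[str]
    test_names: list[str]


def _topology_edges(
    topo: str, nodes: list[str], rng: np.random.Generator
) -> list[tuple[str, str]]:
    n = len(nodes)
    if topo == "clique":
        return list(itertools.combinations(nodes, 2))
    if topo == "chain":
        return [(nodes[i], nodes[i + 1]) for i in range(n - 1)]
    if topo == "star":
        return [(nodes[0], nodes[i]) for i in range(1, n)]
    if topo == "ring":
        return [(nodes[i], nodes[(i + 1) % n]) for i in range(n)]
    if topo == "mixed":
        # spanning path plus a random half of the remaining pairs
        edges = [(nodes[i], nodes[i + 1]) for i in range(n - 1)]
        extra = [
            pair
            for pair in itertools.combinations(nodes, 2)
            if pair not in set(edges)
        ]
        chosen = [pair for pair in extra if rng.random() < 0.5]
        if not chosen:  # guarantee density above a tree
            chosen = [extra[int(rng.integers(len(extra)))]]
        return edges + chosen
    raise ValueError(f"unknown topology {topo!r}")


def _stratified_split(
    layout: list[tuple[str, int]],
    names: list[str],
    train_fraction: float,
    rng: np.random.Generator,
) -> TrainTestSplit:
    """Seeded split stratified by (topology, size) group.

    Per-group training quotas use floor allocation plus largest-remainder
    top-up, so the split composition is identical across seeds; only the
    identity of the chosen complexes varies.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    order: list[tuple[str, int]] = []
    for idx, shape in enumerate(layout):
        if shape not in groups:
            groups[shape] = []
            order.append(shape)
        groups[shape].append(idx)

    n_total = len(layout)
    n_train = int(round(train_fraction * n_total))
    n_train = min(max(n_train, 1), n_total - 1)

    quotas: dict[tuple[str, int], int] = {}
    remainders: list[tuple[float, tuple[str, int]]] = []
    for shape in order:
        exact = train_fraction * len(groups[shape])
        quotas[shape] = int(np.floor(exact))
        remainders.append((exact - quotas[shape], shape))
    short = n_train - sum(quotas.values())
    # stable largest-remainder ordering; first-appearance breaks ties
    remainders.sort(key=lambda x: (-x[0], order.index(x[1])))
    for _, shape in remainders:
        if short <= 0:
            break
        if quotas[shape] < len(groups[shape]):
            quotas[shape] += 1
            short -= 1
    # over-allocation cannot occur with floors, but guard the total anyway
    assert sum(quotas.values()) == n_train, "split quota mismatch"

    train_idx: set[int] = set()
    for shape in order:
        idxs = groups[shape]
        picked = rng.permutation(len(idxs))[: quotas[shape]]
        train_idx.update(idxs[i] for i in picked)
    train_names = [names[i] for i in sorted(train_idx)]
    test_names = [names[i] for i in range(n_total) if i not in train_idx]
    return TrainTestSplit(train_names=train_names, test_names=test_names)


def generate(
    config: PlantedNetworkConfig,
) -> tuple[WeightedNetwork, ComplexCollection, TrainTestSplit]:
    """Build the planted network, its ground truth, and a train/test split.

    Every planted complex is internally connected with at least 3 nodes,
    so with ``disconnected=True`` the ground truth passes gold-standard
    preprocessing unchanged and the number of connected components equals
    the number of complexes.
    """
    rng = np.random.default_rng(config.rng_seed)
    layout = config.resolved_layout(rng)
    net = WeightedNetwork()
    collection = ComplexCollection()
    wlo, whi = config.intra_weight_range
    for idx, (topo, size) in enumerate(layout):
        nodes = [f"C{idx:02d}N{j:02d}" for j in range(size)]
        for node in nodes:
            net.add_node(node)
        for u, v in _topology_edges(topo, nodes, rng):
            w = wlo if wlo == whi else float(rng.uniform(wlo, whi))
            net.add_edge(u, v, w)
        collection.append(f"Cx{idx + 1}", nodes)

    if not config.disconnected and config.inter_edge_prob > 0:
        ilo, ihi = config.inter_weight_range
        sets = collection.member_sets
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                for u in sorted(sets[i]):
                    for v in sorted(sets[j]):
                        if rng.random() < config.inter_edge_prob:
                            w = ilo if ilo == ihi else float(rng.uniform(ilo, ihi))
                            net.add_edge(u, v, w)

    split = _stratified_split(
        layout, collection.names, config.train_fraction, rng
    )
    return net, collection, split


def fig5_preset() -> PlantedNetworkConfig:
    """Toy-scale preset: 14 disjoint complexes, 62 nodes, 78 edges.

    The layout mixes rings and cliques of 4-5 nodes at unit edge weight
    and splits 7/7 (stratified by shape).  The exact adjacency of the
    original toy is not published; this preset reproduces its scale
    (node/edge/complex counts), its disconnectedness, and its mixed
    sparse/dense character.
    """
    layout = (
        [("ring", 4)] * 5
        + [("ring", 5)] * 4
        + [("clique", 4)] * 3
        + [("clique", 5)] * 2
    )
    return PlantedNetworkConfig(
        size_range=(4, 5),
        intra_weight_range=(1.0, 1.0),
        disconnected=True,
        train_fraction=0.5,
        layout=tuple(layout),
    )


def fig1_network() -> tuple[WeightedNetwork, ComplexCollection]:
    """Hand-built 7-node, 11-edge fixture for golden trajectory tests.

    The known complex is {A, B, C, E}.  The seed edge (A, B) has density
    0.8, and the weights are chosen so the growth trajectory visits the
    densities 0.8 -> 0.57 -> 0.38 while the decoy subgraphs {A,B,D},
    {A,B,C,D} and {A,B,C,G} sit at 0.33, 0.35 and 0.35.  Only those
    densities are pinned; the individual weights are fixture choices.
    """
    edges = [
        ("A", "B", 0.8),
        ("A", "C", 0.5),
        ("B", "C", 0.41),
        ("B", "D", 0.19),
        ("C", "D", 0.2),
        ("C", "E", 0.57),
        ("C", "G", 0.39),
        ("E", "F", 0.5),
        ("D", "F", 0.25),
        ("D", "G", 0.3),
        ("F", "G", 0.4),
    ]
    net = WeightedNetwork.from_edges(edges)
    complexes = ComplexCollection()
    complexes.append("Cx1", {"A", "B", "C", "E"})
    return net, complexes
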