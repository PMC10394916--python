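"""Grow candidate complexes from seed edges using value-table lookups only.

Prediction is training-free: from each node's heaviest edge, the subgraph
repeatedly adds the neighbor whose tentative state has the highest table
value, continuing while that value is at least the current subgraph's
value (equal values continue growth) and stopping when every neighbor
would strictly lower it.  Each seed grows independently, so the work is
embarrassingly parallel across seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from joblib import Parallel, delayed

from .network_io import WeightedNetwork
from .state_value import ValueTable, density

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateComplex",
    "select_prediction_seed_edge",
    "grow_candidate",
    "predict_all",
    "sort_candidates",
]

DEFAULT_MAX_SIZE = 100


@dataclass(frozen=True)
class CandidateComplex:
    """A grown subgraph: members, final-state value score, provenance."""

    members: frozenset
    score: float
    seed: tuple[str, str]
    trajectory: tuple[str, ...]  # nodes in the order they were added

    def sort_key(self) -> tuple:
        return (-self.score, tuple(sorted(self.members)))


def select_prediction_seed_edge(
    node: str, network: WeightedNetwork
) -> tuple[str, str] | None:
    """The node plus its highest-weight neighbor (lexicographic tie-break);
    ``None`` for nodes with no edges."""
    nbrs = network.neighbors(node)
    if not nbrs:
        logger.info("node %r is isolated; no seed edge", node)
        return None
    partner = min(nbrs, key=lambda n: (-network.weight(node, n), n))
    return (node, partner)


def grow_candidate(
    seed: tuple[str, str],
    table: ValueTable,
    network: WeightedNetwork,
    max_size: int | None = DEFAULT_MAX_SIZE,
) -> CandidateComplex:
    """Greedy value walk from a seed edge.

    At each step the neighbor whose tentative subgraph has the highest
    table value is selected (lexicographic tie-break); growth continues
    while that value is greater than or equal to the current subgraph's
    value and stops when it is strictly lower.  ``max_size`` caps runaway
    plateaus; ``None`` disables the cap.
    """
    u, v = seed
    if not network.has_edge(u, v):
        raise ValueError(f"seed edge {u}-{v} not in network")
    state = density({u, v}, network)
    current_value = table.lookup(state.d)
    added: list[str] = []
    while max_size is None or state.n < max_size:
        neighbors = sorted(network.subgraph_neighbors(state.members))
        if not neighbors:
            break
        best_nbr = None
        best_state = None
        best_value = None
        for nbr in neighbors:
            tentative = state.with_node(nbr, network)
            value = table.lookup(tentative.d)
            if best_value is None or value > best_value:
                best_nbr, best_state, best_value = nbr, tentative, value
        if best_value < current_value:
            break
        state = best_state
        current_value = best_value
        added.append(best_nbr)
    return CandidateComplex(
        members=state.members,
        score=current_value,
        seed=(u, v),
        trajectory=tuple(added),
    )


def sort_candidates(candidates: list[CandidateComplex]) -> list[CandidateComplex]:
    return sorted(candidates, key=CandidateComplex.sort_key)


def _grow_batch(
    seeds: list[tuple[str, str]],
    table: ValueTable,
    network: WeightedNetwork,
    max_size: int | None,
) -> list[CandidateComplex]:
    return [grow_candidate(s, table, network, max_size) for s in seeds]


def predict_all(
    network: WeightedNetwork,
    table: ValueTable,
    workers: int = 1,
    max_size: int | None = DEFAULT_MAX_SIZE,
) -> list[CandidateComplex]:
    """One growth per node's seed edge over the whole network.

    Distinct nodes sharing a seed edge grow the same subgraph, so seeds
    are deduplicated before growth, and candidates with identical member
    sets are deduplicated afterwards.  The output ordering (score
    descending, then members) is independent of the worker count.
    """
    seen_edges: set = set()
    seeds: list[tuple[str, str]] = []
    for node in sorted(network.nodes):
        seed = select_prediction_seed_edge(node, network)
        if seed is None:
            continue
        key = frozenset(seed)
        if key in seen_edges:
            continue
        seen_edges.add(key)
        seeds.append(seed)

    if workers <= 1 or len(seeds) < 2:
        grown = _grow_batch(seeds, table, network, max_size)
    else:
        chunks = [seeds[i::workers] for i in range(workers)]
        chunks = [c for c in chunks if c]
        results = Parallel(n_jobs=len(chunks))(
            delayed(_grow_batch)(chunk, table, network, max_size)
            for chunk in chunks
        )
        grown = [cand for batch in results for cand in batch]

    unique: dict[frozenset, CandidateComplex] = {}
    for cand in sorted(grown, key=CandidateComplex.sort_key):
        if cand.members not in unique:
            unique[cand.members] = cand
    return sort_candidates(list(unique.values()))
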