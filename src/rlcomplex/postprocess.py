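"""Merge highly overlapping candidates and pick the overlap threshold.

Two candidates qualify for merging when both of their intersection ratios
exceed a threshold ``t`` (a two-sided overlap criterion).  Merging retains
whichever of {first, second, union} scores highest under the value table,
and repeats until no qualifying pair remains.  A threshold sweep reruns
the merge across a grid and keeps the threshold maximizing the
matching-based F-score against the known complexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .evaluation import fmmf
from .network_io import ComplexCollection, WeightedNetwork
from .prediction import CandidateComplex, sort_candidates
from .state_value import ValueTable, density

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapThresholdSweep",
    "qi_overlap",
    "merge_candidates",
    "sweep_thresholds",
    "default_threshold_grid",
]


def default_threshold_grid() -> list[float]:
    """0.2 to 0.9 in steps of 0.025 (inclusive of both ends)."""
    return [round(0.2 + 0.025 * i, 3) for i in range(29)]


@dataclass
class OverlapThresholdSweep:
    thresholds: list[float] = field(default_factory=list)
    fmmf_per_threshold: list[float] = field(default_factory=list)

    @property
    def best_threshold(self) -> float:
        """Threshold attaining the max F-score; lowest threshold on ties."""
        if not self.thresholds:
            raise ValueError("empty sweep")
        best = max(self.fmmf_per_threshold)
        for t, f in sorted(zip(self.thresholds, self.fmmf_per_threshold)):
            if f == best:
                return t
        raise AssertionError("unreachable")


def qi_overlap(cp: frozenset | set, ck: frozenset | set, t: float) -> bool:
    """True iff both intersection ratios strictly exceed ``t``."""
    if not cp or not ck:
        raise ValueError("qi_overlap requires nonempty sets")
    if not 0 < t < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    inter = len(set(cp) & set(ck))
    return inter / len(cp) > t and inter / len(ck) > t


def _retain(
    a: CandidateComplex,
    b: CandidateComplex,
    union: CandidateComplex,
) -> CandidateComplex:
    """Highest-scoring of {a, b, union}; ties prefer the union, then the
    larger member set, then the lexicographically smaller one."""
    best_score = max(a.score, b.score, union.score)
    if union.score == best_score:
        return union
    tied = [c for c in (a, b) if c.score == best_score]
    if len(tied) == 1:
        return tied[0]
    if len(a.members) != len(b.members):
        return a if len(a.members) > len(b.members) else b
    return min(tied, key=lambda c: tuple(sorted(c.members)))


def merge_candidates(
    candidates: list[CandidateComplex],
    t: float,
    table: ValueTable,
    network: WeightedNetwork,
) -> list[CandidateComplex]:
    """Collapse overlapping candidates until no pair qualifies at ``t``.

    The working list is kept in canonical order (score descending, then
    members); each round takes the highest-scoring qualifying pair,
    scores the union by a value-table lookup at its density bin, and
    keeps the single best of the three.  Terminates because every round
    removes one candidate.
    """
    work = sort_candidates(_dedup(candidates))
    while True:
        pair = None
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                if qi_overlap(work[i].members, work[j].members, t):
                    pair = (i, j)
                    break
            if pair:
                break
        if pair is None:
            return work
        i, j = pair
        a, b = work[i], work[j]
        union_members = a.members | b.members
        union = CandidateComplex(
            members=union_members,
            score=table.lookup(density(union_members, network).d),
            seed=a.seed,
            trajectory=a.trajectory,
        )
        survivor = _retain(a, b, union)
        work = [c for k, c in enumerate(work) if k not in (i, j)]
        work.append(survivor)
        work = sort_candidates(_dedup(work))


def _dedup(candidates: list[CandidateComplex]) -> list[CandidateComplex]:
    seen: dict[frozenset, CandidateComplex] = {}
    for cand in sort_candidates(list(candidates)):
        if cand.members not in seen:
            seen[cand.members] = cand
    return list(seen.values())


def sweep_thresholds(
    candidates: list[CandidateComplex],
    known: ComplexCollection,
    table: ValueTable,
    network: WeightedNetwork,
    thresholds: list[float] | None = None,
) -> OverlapThresholdSweep:
    """Merge at each threshold and score the result against ``known``.

    Returns the full F-score curve; ``best_threshold`` is its argmax
    (lowest threshold on ties).  A threshold whose merge leaves no
    candidates scores 0.
    """
    if thresholds is None:
        thresholds = default_threshold_grid()
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    sweep = OverlapThresholdSweep()
    for t in thresholds:
        merged = merge_candidates(candidates, t, table, network)
        member_sets = [c.members for c in merged]
        if member_sets and len(known) > 0:
            _, _, fscore = fmmf(member_sets, known)
        else:
            fscore = 0.0
        sweep.thresholds.append(t)
        sweep.fmmf_per_threshold.append(fscore)
        logger.info("threshold %.3f -> %d candidates, F %.4f",
                    t, len(merged), fscore)
    return sweep
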