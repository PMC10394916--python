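"""Cluster-vs-gold-standard metrics for predicted complex collections.

All metrics take a list of predicted node sets and a known collection and
return values in [0, 1].  ``evaluate_all`` first drops predicted nodes
that never appear in any known complex (and then undersized predictions),
mirroring the preprocessing floor, before computing the full suite:

* FMM precision / recall / F-score — maximum-weight bipartite matching
  with F-similarity edge weights;
* CMMF — community-wise best-match F-similarity averages;
* SPA / UnSPA — (unbiased) geometric mean of clustering sensitivity and
  positive predictive value from the overlap-count matrix;
* Qi et al. F-score — fraction of complexes with a two-sided
  affinity-ratio match;
* F-grand / F-weighted k-clique — precision/recall over the k-member
  subsets of complexes, aggregated across k.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .network_io import ComplexCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "filter_to_known_nodes",
    "f_similarity",
    "fmmf",
    "cmmf",
    "spa_unspa",
    "qi_fscore",
    "kclique_fscores",
    "evaluate_all",
]

NodeSets = Sequence[frozenset] | Sequence[set]


def _as_sets(collection) -> list[frozenset]:
    if isinstance(collection, ComplexCollection):
        return collection.member_sets
    return [frozenset(c) for c in collection]


def _harmonic(p: float, r: float) -> float:
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


@dataclass
class EvaluationReport:
    fmm_precision: float = 0.0
    fmm_recall: float = 0.0
    fmm_fscore: float = 0.0
    cmmf: float = 0.0
    unspa: float = 0.0
    spa: float = 0.0
    qi_f1: float = 0.0
    f_grand_kclique: float = 0.0
    f_weighted_kclique: float = 0.0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"metric {f.name}={v} outside [0, 1]")


def filter_to_known_nodes(
    predicted: NodeSets,
    known: ComplexCollection | NodeSets,
    min_size: int = 3,
) -> list[frozenset]:
    """Intersect each prediction with the known-node universe; drop sets
    that fall below ``min_size``."""
    universe: set = set()
    for c in _as_sets(known):
        universe |= c
    out: list[frozenset] = []
    for pred in predicted:
        reduced = frozenset(pred) & universe
        if len(reduced) >= min_size:
            out.append(frozenset(reduced))
    return out


def f_similarity(cp: Iterable[str], ck: Iterable[str]) -> float:
    """Harmonic mean of the two intersection ratios; 0 when disjoint."""
    cp, ck = frozenset(cp), frozenset(ck)
    if not cp or not ck:
        raise ValueError("f_similarity requires nonempty sets")
    inter = len(cp & ck)
    if inter == 0:
        return 0.0
    return _harmonic(inter / len(cp), inter / len(ck))


def _check_sides(predicted: list[frozenset], known: list[frozenset]) -> None:
    if not predicted or not known:
        raise ValueError("metrics require nonempty predicted and known sides")


def fmmf(
    predicted: NodeSets, known: ComplexCollection | NodeSets
) -> tuple[float, float, float]:
    """Matching-based F-score.

    ``W`` is the weight of a maximum-weight matching in the complete
    bipartite graph whose edges carry pairwise F-similarities; recall is
    ``W / #known``, precision is ``W / #predicted``, and the F-score is
    their harmonic mean.
    """
    pred = _as_sets(predicted)
    ref = _as_sets(known)
    _check_sides(pred, ref)
    sim = np.zeros((len(pred), len(ref)))
    for i, p in enumerate(pred):
        for j, k in enumerate(ref):
            sim[i, j] = f_similarity(p, k)
    rows, cols = linear_sum_assignment(sim, maximize=True)
    weight = float(sim[rows, cols].sum())
    precision = weight / len(pred)
    recall = weight / len(ref)
    return precision, recall, _harmonic(precision, recall)


def cmmf(predicted: NodeSets, known: ComplexCollection | NodeSets) -> float:
    """Harmonic mean of the two community-wise best-match averages."""
    pred = _as_sets(predicted)
    ref = _as_sets(known)
    _check_sides(pred, ref)
    recall_side = float(
        np.mean([max(f_similarity(k, p) for p in pred) for k in ref])
    )
    precision_side = float(
        np.mean([max(f_similarity(p, k) for k in ref) for p in pred])
    )
    return _harmonic(precision_side, recall_side)


def spa_unspa(
    predicted: NodeSets, known: ComplexCollection | NodeSets
) -> tuple[float, float]:
    """Sensitivity/PPV accuracies from the overlap-count matrix.

    With ``T[i, j] = |known_i & predicted_j|``:
    ``Sn = sum_i max_j T / sum_i |known_i|``,
    ``PPV = sum_j max_i T / sum_ij T``, ``SPA = sqrt(Sn * PPV)``; the
    unbiased variant averages the per-complex ratios instead.
    """
    pred = _as_sets(predicted)
    ref = _as_sets(known)
    _check_sides(pred, ref)
    T = np.zeros((len(ref), len(pred)))
    for i, k in enumerate(ref):
        for j, p in enumerate(pred):
            T[i, j] = len(k & p)
    known_sizes = np.array([len(k) for k in ref], dtype=float)
    pred_sizes = np.array([len(p) for p in pred], dtype=float)

    sn = float(T.max(axis=1).sum() / known_sizes.sum())
    total = float(T.sum())
    ppv = float(T.max(axis=0).sum() / total) if total > 0 else 0.0
    spa = math.sqrt(sn * ppv)

    sn_u = float(np.mean(T.max(axis=1) / known_sizes))
    ppv_u = float(np.mean(T.max(axis=0) / pred_sizes))
    unspa = math.sqrt(sn_u * ppv_u)
    return spa, unspa


def qi_fscore(
    predicted: NodeSets,
    known: ComplexCollection | NodeSets,
    tau: float = 0.25,
) -> float:
    """F-score over two-sided affinity matches.

    A predicted/known pair matches when both intersection ratios strictly
    exceed ``tau``; precision and recall are the fractions of predicted
    (resp. known) complexes with at least one match.
    """
    pred = _as_sets(predicted)
    ref = _as_sets(known)
    _check_sides(pred, ref)

    def matches(p: frozenset, k: frozenset) -> bool:
        inter = len(p & k)
        return inter / len(p) > tau and inter / len(k) > tau

    precision = sum(
        1 for p in pred if any(matches(p, k) for k in ref)
    ) / len(pred)
    recall = sum(
        1 for k in ref if any(matches(p, k) for p in pred)
    ) / len(ref)
    return _harmonic(precision, recall)


def _ksets(sets: list[frozenset], k: int, size_cap: int) -> set[frozenset]:
    out: set[frozenset] = set()
    for members in sets:
        if len(members) > size_cap:
            continue
        if len(members) < k:
            continue
        out.update(frozenset(c) for c in itertools.combinations(sorted(members), k))
    return out


def kclique_fscores(
    predicted: NodeSets,
    known: ComplexCollection | NodeSets,
    k_max: int = 10,
    size_cap: int = 20,
) -> tuple[float, float]:
    """Precision/recall over the k-member subsets of complexes.

    For each k in 2..``k_max`` the complexes are decomposed into their
    k-member subsets and scored set-against-set; per-k F-scores are then
    averaged unweighted (grand) and weighted by the known k-set counts.
    Complexes larger than ``size_cap`` are excluded from enumeration with
    a warning (combinatorial guard); k values with no sets on either side
    are skipped.
    """
    pred = _as_sets(predicted)
    ref = _as_sets(known)
    _check_sides(pred, ref)
    for members in itertools.chain(pred, ref):
        if len(members) > size_cap:
            logger.warning(
                "complex of size %d exceeds size cap %d; excluded from "
                "k-set enumeration", len(members), size_cap,
            )
    f_values: list[float] = []
    weights: list[int] = []
    for k in range(2, k_max + 1):
        pred_k = _ksets(pred, k, size_cap)
        known_k = _ksets(ref, k, size_cap)
        if not pred_k and not known_k:
            continue
        if not pred_k or not known_k:
            f_k = 0.0
        else:
            inter = len(pred_k & known_k)
            f_k = _harmonic(inter / len(pred_k), inter / len(known_k))
        f_values.append(f_k)
        weights.append(len(known_k))
    if not f_values:
        return 0.0, 0.0
    f_grand = float(np.mean(f_values))
    total_w = sum(weights)
    if total_w == 0:
        f_weighted = 0.0
    else:
        f_weighted = float(
            sum(f * w for f, w in zip(f_values, weights)) / total_w
        )
    return f_grand, f_weighted


def evaluate_all(
    predicted: NodeSets,
    known: ComplexCollection | NodeSets,
    qi_tau: float = 0.25,
    k_max: int = 10,
    size_cap: int = 20,
    min_size: int = 3,
) -> EvaluationReport:
    """Node-filter then compute every metric.

    If filtering removes every prediction the report is all zeros (with a
    warning) rather than an error.
    """
    filtered = filter_to_known_nodes(predicted, known, min_size=min_size)
    if not filtered:
        logger.warning("all predictions removed by node filtering; "
                       "reporting zeros")
        return EvaluationReport()
    precision, recall, fscore = fmmf(filtered, known)
    spa, unspa = spa_unspa(filtered, known)
    f_grand, f_weighted = kclique_fscores(
        filtered, known, k_max=k_max, size_cap=size_cap
    )
    return EvaluationReport(
        fmm_precision=precision,
        fmm_recall=recall,
        fmm_fscore=fscore,
        cmmf=cmmf(filtered, known),
        unspa=unspa,
        spa=spa,
        qi_f1=qi_fscore(filtered, known, tau=qi_tau),
        f_grand_kclique=f_grand,
        f_weighted_kclique=f_weighted,
    )
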