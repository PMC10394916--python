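"""Independent brute-force oracles used to pin expected metric values.

These deliberately avoid the package's implementations: matchings are
enumerated over permutations, and the similarity/accuracy formulas are
restated from first principles.
"""

from __future__ import annotations

import itertools
import math


def fsim(a: set, b: set) -> float:
    inter = len(set(a) & set(b))
    if inter == 0:
        return 0.0
    p = inter / len(a)
    r = inter / len(b)
    return 2 * p * r / (p + r)


def brute_force_matching_weight(predicted: list[set], known: list[set]) -> float:
    """Max-weight bipartite matching by exhaustive permutation search."""
    n_p, n_k = len(predicted), len(known)
    best = 0.0
    if n_p <= n_k:
        for perm in itertools.permutations(range(n_k), n_p):
            w = sum(fsim(predicted[i], known[j]) for i, j in enumerate(perm))
            best = max(best, w)
    else:
        for perm in itertools.permutations(range(n_p), n_k):
            w = sum(fsim(predicted[i], known[j]) for j, i in enumerate(perm))
            best = max(best, w)
    return best


def brute_force_fmmf(predicted: list[set], known: list[set]):
    w = brute_force_matching_weight(predicted, known)
    precision = w / len(predicted)
    recall = w / len(known)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def brute_force_cmmf(predicted: list[set], known: list[set]) -> float:
    rec = sum(max(fsim(k, p) for p in predicted) for k in known) / len(known)
    prec = sum(max(fsim(p, k) for k in known) for p in predicted) / len(predicted)
    if prec + rec == 0:
        return 0.0
    return 2 * prec * rec / (prec + rec)


def brute_force_spa_unspa(predicted: list[set], known: list[set]):
    T = [[len(set(k) & set(p)) for p in predicted] for k in known]
    sn = sum(max(row) for row in T) / sum(len(k) for k in known)
    total = sum(sum(row) for row in T)
    cols = list(zip(*T))
    ppv = (sum(max(c) for c in cols) / total) if total else 0.0
    spa = math.sqrt(sn * ppv)
    sn_u = sum(max(row) / len(k) for row, k in zip(T, known)) / len(known)
    ppv_u = sum(max(c) / len(p) for c, p in zip(cols, predicted)) / len(predicted)
    unspa = math.sqrt(sn_u * ppv_u)
    return spa, unspa


def unrolled_episode_values(
    steps: list[tuple[float, list[tuple[float, float]]]],
    gamma: float = 0.5,
):
    """Hand-unroll a sequence of max-over-action updates.

    ``steps`` is a list of (current-bin value placeholder, actions) where
    each action is (reward, next-state value as read before the update).
    Returns the written values, one per step.
    """
    written = []
    for _, actions in steps:
        written.append(max(r + gamma * v for r, v in actions))
    return written
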