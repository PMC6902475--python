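"""Independent oracles used to cross-check the package implementation.

Each oracle is written from the defining recurrence/enumeration, not from
the package's code path: set-based Jaccard, Gotoh dynamic programming for
local alignment, exhaustive Wang S-value recursion, pairwise-count AUC and
cutoff-sweep AUC.
"""

from __future__ import annotations

import numpy as np


def jaccard_sets(a: set[int], b: set[int]) -> float:
    """Jaccard similarity by literal set operations (0 on two empty sets)."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def smith_waterman_gotoh(
    s1: str, s2: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Local alignment score by the Gotoh affine-gap recurrence.

    A gap of length L costs gap_open + (L-1)*gap_extend.
    """
    n, m = len(s1), len(s2)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in s1 (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in s2 (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            sub = H[i - 1, j - 1] + matrix[s1[i - 1], s2[j - 1]]
            H[i, j] = max(0.0, sub, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def wang_svalues(term: str, parents: dict[str, list[tuple[str, float]]]):
    """All-paths S-value enumeration for Wang's measure (exponential, tiny DAGs)."""
    svals: dict[str, float] = {}

    def walk(t: str, s: float) -> None:
        if s > svals.get(t, 0.0):
            svals[t] = s
        for parent, w in parents.get(t, []):
            walk(parent, s * w)

    walk(term, 1.0)
    return svals


def wang_pair(term_a: str, term_b: str, parents) -> float:
    sa = wang_svalues(term_a, parents)
    sb = wang_svalues(term_b, parents)
    common = set(sa) & set(sb)
    if not common:
        return 0.0
    return sum(sa[t] + sb[t] for t in common) / (
        sum(sa.values()) + sum(sb.values())
    )


def auc_pair_count(y: np.ndarray, scores: np.ndarray) -> float:
    """Normalized Mann-Whitney statistic: P(score_pos > score_neg) + 0.5 ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def auc_cutoff_sweep(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by sweeping the cutoff over all distinct scores (trapezoid rule)."""
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    P = (y == 1).sum()
    N = (y == 0).sum()
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = scores >= t
        tpr.append(((pred) & (y == 1)).sum() / P)
        fpr.append(((pred) & (y == 0)).sum() / N)
    return float(np.trapezoid(tpr, fpr))
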