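"""Independent brute-force oracles used to check the implementation.

Each oracle takes the slow-but-obviously-correct route (full enumeration,
direct centroid algebra, dense eigendecomposition) and is kept free of any
code path it is used to verify.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def mwu_exact_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating rank configurations.

    Returns (U of the first sample, p).  The permutation distribution of U
    is symmetric about n1*n2/2, so the two-sided p is the fraction of
    label assignments at least as far from the center as the observed U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)

    def u_stat(first_idx: tuple[int, ...]) -> float:
        a = pooled[list(first_idx)]
        b = np.delete(pooled, list(first_idx))
        greater = (a[:, None] > b[None, :]).sum()
        ties = (a[:, None] == b[None, :]).sum()
        return greater + 0.5 * ties

    u_obs = u_stat(tuple(range(n1)))
    center = n1 * (n - n1) / 2.0
    dev = abs(u_obs - center)
    hits = sum(
        1
        for idx in itertools.combinations(range(n), n1)
        if abs(u_stat(idx) - center) >= dev - 1e-12
    )
    return u_obs, hits / comb(n, n1)


def permanova_f_centroid(X: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F via explicit centroid sums of squares (Euclidean only)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, a = len(X), len(uniq)
    grand = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum()
    ss_within = 0.0
    for g in uniq:
        sub = X[labels == g]
        ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return 0.0 if ss_between <= 0 else np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_exhaustive_p(X: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p: fraction of distinct label assignments whose
    centroid pseudo-F is >= the observed one."""
    labels = np.asarray(labels)
    f_obs = permanova_f_centroid(X, labels)
    seen = set()
    hits = total = 0
    for perm in itertools.permutations(range(len(labels))):
        key = tuple(labels[list(perm)])
        if key in seen:
            continue
        seen.add(key)
        total += 1
        if permanova_f_centroid(X, np.asarray(key)) >= f_obs - 1e-12:
            hits += 1
    return hits / total


def bh_stepup(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def leading_eigenvector(weights: np.ndarray) -> np.ndarray:
    """Unit-norm non-negative leading eigenvector via dense eigh."""
    lam, vec = np.linalg.eigh(np.abs(weights))
    v = vec[:, np.argmax(lam)]
    if v.sum() < 0:
        v = -v
    return np.abs(v) / np.linalg.norm(v)


def threshold_edges_bruteforce(corr: np.ndarray, k: int) -> set[tuple[int, int]]:
    """Top-k |weight| edges by exhaustive sort (lexicographic tie-break)."""
    p = corr.shape[0]
    edges = [(i, j) for i in range(p) for j in range(i + 1, p)]
    edges.sort(key=lambda e: (-abs(corr[e]), e[0], e[1]))
    return set(edges[:k])
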