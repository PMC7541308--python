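"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (loops, exact rational arithmetic,
Monte-Carlo) and shares no code with the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def tom_triple_loop(A: np.ndarray, denom: str) -> np.ndarray:
    """Topological overlap by explicit triple loop."""
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = 0.0
            for u in range(n):
                l_ij += A[i, u] * A[u, j]
            f = min(k[i], k[j]) if denom == "min" else (k[i] + k[j]) / 2.0
            omega[i, j] = (l_ij + A[i, j]) / (f + 1.0 - A[i, j])
    return omega


def average_linkage_naive(D: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) average-linkage agglomeration; returns merge list with heights.

    Ties broken by smallest pair of cluster indices (matching the
    lowest-index-first convention).
    """
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean([D[p, q] for p in clusters[a] for q in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def hypergeom_tail_exact(N: int, R: int, n: int, r: int) -> Fraction:
    """P(X >= r) for overlap of a size-R set and a size-n draw from N, exactly."""
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(r, min(R, n) + 1):
        acc += Fraction(comb(R, x) * comb(N - R, n - x), total)
    return acc


def tukey_sf_monte_carlo(q: float, k: int, df: int, n_draws: int, rng) -> float:
    """P(Q > q) for the studentized range by direct simulation under H0."""
    z = rng.standard_normal((n_draws, k))
    rng_range = z.max(axis=1) - z.min(axis=1)
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    return float(np.mean(rng_range / s > q))


def bicor_direct(x, y) -> float:
    """Biweight midcorrelation evaluated term by term from the definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a, b = weights(x), weights(y)
    return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))


def anova_f_textbook(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """One-way ANOVA F from sums of squares, straight from the definitions."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k = len(groups)
    n = len(all_vals)
    return (ssb / (k - 1)) / (sse / (n - k)), k - 1, n - k
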