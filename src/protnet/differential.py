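"""Per-protein one-way ANOVA with Tukey HSD post-hoc tests and volcano classes.

Four design cells (WT-young, KO-young, WT-old, KO-old) are compared per
protein with the standard one-way ANOVA F = MSB/MSE on (k-1, N-k) degrees of
freedom, followed by all six pairwise Tukey tests

    q_ij = |m_i - m_j| / sqrt( (MSE/2) * (1/n_i + 1/n_j) )

with p-values from the studentized range distribution.  Volcano classes call
a protein increased/decreased on a contrast when the contrast p-value is at
or below ``p_threshold`` and the log2 ratio clears ``log2fc_threshold``
(default log2(1.25), i.e. a minimum 25% linear fold change).

The studentized range CDF is evaluated by Gauss-Legendre quadrature (the
range-of-k-normals CDF on a fine grid, then integrated over the scale
distribution of sqrt(chi^2_df / df)), which is orders of magnitude faster
than per-value adaptive integration and accurate to ~1e-6.
"""

from __future__ import annotations

import itertools
import logging
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from scipy.special import gammaln

from .types import AbundanceMatrix

logger = logging.getLogger("protnet")

GROUP_ORDER = ("WT-young", "KO-young", "WT-old", "KO-old")
# displayed contrasts: (name, numerator group, denominator group)
CONTRASTS = (
    ("KO_vs_WT_young", "KO-young", "WT-young"),
    ("KO_vs_WT_old", "KO-old", "WT-old"),
    ("old_vs_young_WT", "WT-old", "WT-young"),
    ("old_vs_young_KO", "KO-old", "KO-young"),
)


# ---------------------------------------------------------------------------
# studentized range distribution
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _range_cdf_spline(k: int) -> CubicSpline:
    """CDF of the range of k iid standard normals, splined on w in [0, 20]."""
    z_nodes, z_weights = np.polynomial.legendre.leggauss(120)
    lo, hi = -8.5, 8.5
    z = (hi - lo) / 2 * z_nodes + (hi + lo) / 2
    wz = (hi - lo) / 2 * z_weights
    phi = stats.norm.pdf(z)
    Phi = stats.norm.cdf(z)
    w_grid = np.linspace(0.0, 20.0, 2001)
    # P(range <= w) = k * int phi(z) [Phi(z) - Phi(z-w)]^(k-1) dz
    inner = Phi[None, :] - stats.norm.cdf(z[None, :] - w_grid[:, None])
    cdf = k * (wz * phi * np.clip(inner, 0.0, None) ** (k - 1)).sum(axis=1)
    cdf = np.clip(cdf, 0.0, 1.0)
    return CubicSpline(w_grid, cdf)


@lru_cache(maxsize=64)
def _scale_nodes(df: int, n_nodes: int = 80) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes/weights for s ~ sqrt(chi2_df / df), density-weighted."""
    s_hi = math.sqrt(stats.chi2.ppf(1.0 - 1e-12, df) / df)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    s = s_hi / 2 * (nodes + 1.0)
    ws = s_hi / 2 * weights
    log_dens = (
        (df / 2) * math.log(df) - gammaln(df / 2) - (df / 2 - 1) * math.log(2)
        + (df - 1) * np.log(s) - df * s**2 / 2
    )
    return s, ws * np.exp(log_dens)


def studentized_range_sf(q, k: int, df: int) -> np.ndarray | float:
    """Survival function P(Q > q) of the studentized range (k groups, df error df)."""
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    spline = _range_cdf_spline(int(k))
    s, ws = _scale_nodes(int(df))
    w = np.clip(q_arr[:, None] * s[None, :], 0.0, 20.0)
    cdf = (spline(w) * ws[None, :]).sum(axis=1)
    sf = np.clip(1.0 - cdf, 0.0, 1.0)
    sf[q_arr <= 0] = 1.0
    return float(sf[0]) if np.ndim(q) == 0 else sf


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

def _group_columns(matrix: AbundanceMatrix) -> dict[str, np.ndarray]:
    cols = {g: [] for g in GROUP_ORDER}
    for i, s in enumerate(matrix.samples):
        cols[s.group].append(i)
    return {g: np.asarray(ix, dtype=int) for g, ix in cols.items() if ix}


def anova_tukey(matrix: AbundanceMatrix) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD per complete protein.

    Returns a wide table with one row per protein: group means, F, ANOVA p,
    the six pairwise Tukey p-values, and per-contrast log2 ratios.  Proteins
    with any missing cell are excluded (the analysis runs on the complete
    set); a degenerate protein (MSE = 0 with unequal means) gets p = 0 and a
    ``degenerate`` flag.
    """
    groups = _group_columns(matrix)
    if len(groups) < 2:
        raise ValueError("need at least 2 design groups")
    if any(ix.size < 2 for ix in groups.values()):
        raise ValueError("every group needs at least 2 samples")
    complete = matrix.complete_index()
    n_excluded = matrix.n_proteins - complete.size
    if n_excluded:
        logger.info("differential: excluded %d protein(s) with missing cells", n_excluded)
    X = matrix.values[complete]
    names = [matrix.proteins[i] for i in complete]
    gnames = list(groups)
    k = len(gnames)
    ns = np.array([groups[g].size for g in gnames])
    N = int(ns.sum())
    means = np.column_stack([X[:, groups[g]].mean(axis=1) for g in gnames])
    grand = X.mean(axis=1)
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    sse = np.zeros(len(X))
    for j, g in enumerate(gnames):
        sse += ((X[:, groups[g]] - means[:, [j]]) ** 2).sum(axis=1)
    df_b, df_e = k - 1, N - k
    msb = ssb / df_b
    mse = sse / df_e
    degenerate = mse == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / mse
    F = np.where(degenerate, np.where(ssb > 0, np.inf, 0.0), F)
    anova_p = np.where(
        degenerate, np.where(ssb > 0, 0.0, 1.0), stats.f.sf(F, df_b, df_e)
    )

    out = pd.DataFrame({"protein": names})
    for j, g in enumerate(gnames):
        out[f"mean_{g}"] = means[:, j]
    out["F"] = F
    out["anova_p"] = anova_p
    out["degenerate"] = degenerate

    for (i, gi), (j, gj) in itertools.combinations(enumerate(gnames), 2):
        diff = np.abs(means[:, i] - means[:, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt((mse / 2.0) * (1.0 / ns[i] + 1.0 / ns[j]))
            q = diff / se
        p = np.where(
            mse == 0,
            np.where(diff > 0, 0.0, 1.0),
            studentized_range_sf(np.where(mse == 0, 0.0, q), k, df_e),
        )
        out[f"tukey_p_{gi}__{gj}"] = p
    return out


def _pair_col(a: str, b: str, columns) -> str:
    for col in (f"tukey_p_{a}__{b}", f"tukey_p_{b}__{a}"):
        if col in columns:
            return col
    raise KeyError(f"no Tukey column for pair ({a}, {b})")


def classify_volcano(
    de: pd.DataFrame,
    p_threshold: float = 0.05,
    log2fc_threshold: float = math.log2(1.25),
    volcano_p: str = "tukey",
) -> pd.DataFrame:
    """Long-format volcano table: one row per protein x contrast.

    ``increased``: contrast p <= p_threshold (inclusive) and log2 ratio >
    +log2fc_threshold (strict); ``decreased`` symmetric; else
    ``not_significant``.  The driving p is the contrast's Tukey pairwise p by
    default, or the omnibus ANOVA p with ``volcano_p="anova"``.
    """
    if p_threshold <= 0 or log2fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    rows = []
    for name, num, den in CONTRASTS:
        num_col, den_col = f"mean_{num}", f"mean_{den}"
        if num_col not in de.columns or den_col not in de.columns:
            continue
        ratio = de[num_col].to_numpy() - de[den_col].to_numpy()
        if volcano_p == "anova":
            p = de["anova_p"].to_numpy()
        else:
            p = de[_pair_col(num, den, de.columns)].to_numpy()
        cls = np.where(
            (p <= p_threshold) & (ratio > log2fc_threshold),
            "increased",
            np.where((p <= p_threshold) & (ratio < -log2fc_threshold), "decreased",
                     "not_significant"),
        )
        bh = bh_column(p)
        rows.append(
            pd.DataFrame(
                {
                    "protein": de["protein"],
                    "contrast": name,
                    "log2_ratio": ratio,
                    "p": p,
                    "anova_p": de["anova_p"],
                    "bh_p": bh,
                    "volcano_class": cls,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def bh_column(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (informational column)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
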