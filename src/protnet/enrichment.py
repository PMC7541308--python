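"""Module-trait correlation, cell-type/ontology enrichment, and term clustering.

Module-trait relationships use the biweight midcorrelation of each module
eigenprotein against binary sample traits (genotype KO=1, age old=1), with
the robust weighting disabled on the binary side (a binary vector's mad is
degenerate).  Cell-type enrichment is the one-tailed Fisher exact
(hypergeometric) overlap test with Benjamini-Hochberg correction across all
module x set tests; ontology over-representation additionally reports the
Z-score — the normal approximation to the hypergeometric with finite
population correction:

    Z = (r - n R / N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) )

Enriched terms can be grouped by Cohen's kappa agreement of their gene
memberships, cut at kappa 0.3.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster
from statsmodels.stats.multitest import multipletests

from .network._correlation import bicor, corr_pvalue
from .network._treecut import cluster_tree
from .types import GeneSetCollection

logger = logging.getLogger("protnet")

_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return ""


def module_trait(
    eigenproteins: np.ndarray,
    module_ids: list[int],
    traits: dict[str, np.ndarray],
    stratum: str = "all",
) -> pd.DataFrame:
    """bicor of each eigenprotein against each binary trait, with t-test p."""
    rows = []
    for row, m in enumerate(module_ids):
        me = np.asarray(eigenproteins[row], dtype=float)
        for tname, tvec in traits.items():
            tvec = np.asarray(tvec, dtype=float)
            if tvec.shape != me.shape:
                raise ValueError(f"trait {tname!r} length mismatch")
            n = me.size
            if np.ptp(tvec) == 0:
                logger.warning("trait %s constant in stratum %s; undefined", tname, stratum)
                r, p = np.nan, np.nan
            else:
                r = bicor(me, tvec, robust_x=True, robust_y=False)
                p = corr_pvalue(r, n)
            rows.append(
                {
                    "module": f"M{m}",
                    "trait": tname,
                    "stratum": stratum,
                    "r": r,
                    "p": p,
                    "n": n,
                    "stars": significance_stars(p) if np.isfinite(p) else "",
                }
            )
    return pd.DataFrame(rows)


def module_trait_strata(
    eigenproteins: np.ndarray, module_ids: list[int], samples
) -> pd.DataFrame:
    """Joint and per-age-stratum trait correlations from sample metadata."""
    geno = np.array([1.0 if s.genotype == "KO" else 0.0 for s in samples])
    age = np.array([1.0 if s.age_group == "old" else 0.0 for s in samples])
    tables = [
        module_trait(eigenproteins, module_ids, {"genotype": geno, "age": age}, stratum="all")
    ]
    for age_group in ("young", "old"):
        keep = np.array([s.age_group == age_group for s in samples])
        if keep.sum() >= 3 and np.ptp(geno[keep]) > 0:
            tables.append(
                module_trait(
                    eigenproteins[:, keep], module_ids,
                    {"genotype": geno[keep]}, stratum=age_group,
                )
            )
    return pd.concat(tables, ignore_index=True)


def fisher_celltype(
    module_members: dict[str, list[str]],
    gene_sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """One-tailed hypergeometric overlap of every module with every gene set.

    ``p = P(X >= r)`` for overlap r with N universe, R set size, n module
    size (all after intersection with the universe); BH-adjusted across all
    module x set tests jointly.  The Z-score column carries the normal
    approximation for over-representation ranking.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    N = len(uni)
    rows = []
    for set_name, members in gene_sets.sets.items():
        in_uni = [m for m in members if m in uni_set]
        dropped = len(members) - len(in_uni)
        if dropped:
            logger.info("set %s: %d member(s) outside universe dropped", set_name, dropped)
        R = len(in_uni)
        sset = set(in_uni)
        for mod_name, mod_members in module_members.items():
            mod_in = [p for p in mod_members if p in uni_set]
            n = len(mod_in)
            if R == 0 or n == 0 or N == 0:
                logger.info("skipping %s x %s: empty after universe intersection",
                            mod_name, set_name)
                continue
            r = sum(1 for p in mod_in if p in sset)
            p = float(stats.hypergeom.sf(r - 1, N, R, n))
            rows.append(
                {
                    "module": mod_name,
                    "set": set_name,
                    "N": N,
                    "R": R,
                    "n": n,
                    "overlap": r,
                    "fisher_p": min(p, 1.0),
                    "z_score": _overlap_zscore(N, R, n, r),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["bh_p"] = bh_adjust(df["fisher_p"].to_numpy())
        df["stars"] = [significance_stars(p) for p in df["bh_p"]]
    return df


def _overlap_zscore(N: int, R: int, n: int, r: int) -> float:
    if not (N > 1 and 0 < R < N and 0 < n < N):
        return float("nan")
    expected = n * R / N
    var = n * (R / N) * (1 - R / N) * (1 - (n - 1) / (N - 1))
    if var <= 0:
        return float("nan")
    return float((r - expected) / np.sqrt(var))


def zscore_enrichment(
    module_members: dict[str, list[str]],
    term_sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Z-score over-representation with one-sided normal p (approximate)."""
    df = fisher_celltype(module_members, term_sets, universe)
    if len(df):
        df["z_p"] = stats.norm.sf(df["z_score"].to_numpy())
    return df


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohen_kappa(a_members: set, b_members: set, universe: list[str]) -> float:
    """Chance-corrected agreement of two membership indicators over a universe."""
    N = len(universe)
    a = sum(1 for g in universe if g in a_members and g in b_members)
    b = sum(1 for g in universe if g in a_members and g not in b_members)
    c = sum(1 for g in universe if g not in a_members and g in b_members)
    d = N - a - b - c
    po = (a + d) / N
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / N**2
    if pe == 1.0:
        logger.info("kappa: degenerate identical marginals")
        return 1.0 if b == c == 0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_cluster(
    terms: pd.DataFrame,
    term_sets: GeneSetCollection,
    universe: list[str],
    kappa_threshold: float = 0.3,
) -> pd.DataFrame:
    """Group enriched terms by kappa similarity of their gene memberships.

    ``terms`` needs columns ``set`` (term name) and a p-value column
    (``fisher_p``); the average-linkage tree on ``1 - kappa`` is cut at
    ``1 - kappa_threshold`` and each cluster's representative is its member
    with the smallest p.
    """
    names = list(dict.fromkeys(terms["set"]))
    if len(names) < 2:
        return pd.DataFrame(
            {"set": names, "cluster": [1] * len(names), "representative": [True] * len(names)}
        )
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    membership = {t: set(term_sets.sets.get(t, [])) & uni_set for t in names}
    k = len(names)
    K = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            K[i, j] = K[j, i] = cohen_kappa(membership[names[i]], membership[names[j]], uni)
    diss = np.clip(1.0 - K, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    Z = cluster_tree(diss)
    clusters = fcluster(Z, t=1.0 - kappa_threshold, criterion="distance")
    best_p = terms.groupby("set")["fisher_p"].min()
    out = pd.DataFrame({"set": names, "cluster": clusters.astype(int)})
    out["p"] = out["set"].map(best_p)
    out["representative"] = False
    for c in out["cluster"].unique():
        sub = out[out["cluster"] == c]
        out.loc[sub["p"].idxmin(), "representative"] = True
    return out
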