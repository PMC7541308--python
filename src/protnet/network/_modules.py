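"""Module summaries: eigenproteins, kME, merging, reassignment, missing-protein mapping.

A module eigenprotein is the first principal component of the module's
standardized (per-protein z-scored) log2 abundance profiles — the single
expression pattern that explains the most within-module variance.  kME, the
module membership measure, is the Pearson correlation of a protein's profile
with a module eigenprotein.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster

from ._correlation import bicor, corr_pvalue, pearson_matrix
from ._treecut import cluster_tree

logger = logging.getLogger("protnet")


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def eigenproteins(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """First right singular vector per module, sign-oriented, with var explained.

    Parameters
    ----------
    X
        Complete ``(n_proteins, n_samples)`` log2 abundances.
    labels
        Integer module labels; 0 = unassigned (skipped).

    Returns
    -------
    ME : ``(n_modules, n_samples)`` unit-norm eigenprotein scores, one row per
        module id in ``module_ids`` order.
    var_explained : fraction of total standardized variance captured.
    module_ids : sorted module ids present (excluding 0).
    """
    labels = np.asarray(labels)
    module_ids = sorted(int(m) for m in np.unique(labels) if m != 0)
    n_samples = X.shape[1]
    ME = np.empty((len(module_ids), n_samples))
    var_explained = np.empty(len(module_ids))
    for row, m in enumerate(module_ids):
        sub = _standardize_rows(X[labels == m])
        if sub.shape[0] < 2:
            logger.warning("module %d has < 2 proteins; eigenprotein = standardized mean", m)
            v = sub.mean(axis=0)
            v = v / (np.linalg.norm(v) or 1.0)
            ME[row], var_explained[row] = v, 1.0
            continue
        _, s, Vt = np.linalg.svd(sub, full_matrices=False)
        v = Vt[0]
        mean_profile = sub.mean(axis=0)
        if float(v @ mean_profile) < 0:
            v = -v
        ME[row] = v
        var_explained[row] = float(s[0] ** 2 / (s**2).sum())
    return ME, var_explained, module_ids


def kme(X: np.ndarray, ME: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson kME of every protein against every eigenprotein, with t-test p-values."""
    Xz = _standardize_rows(np.asarray(X, dtype=float))
    n = X.shape[1]
    MEz = _standardize_rows(ME)
    K = np.clip(Xz @ MEz.T / n, -1.0, 1.0)
    P = corr_pvalue(K, n)
    return K, np.asarray(P)


def relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber modules 1..k by decreasing size (ties: smallest old id first)."""
    labels = np.asarray(labels)
    ids = [int(m) for m in np.unique(labels) if m != 0]
    ids.sort(key=lambda m: (-(labels == m).sum(), m))
    out = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def merge_modules(
    X: np.ndarray, labels: np.ndarray, merge_cut_height: float = 0.07
) -> tuple[np.ndarray, list[list[int]]]:
    """Merge modules whose eigenproteins are closer than ``merge_cut_height``.

    Eigenproteins are clustered by average linkage on ``1 - cor``; all modules
    inside a subtree below the cut height collapse into one.  Eigenproteins
    are recomputed and the step repeats until stable.  Returns the merged
    labels (renumbered by size) and a history of merge groups.
    """
    labels = np.asarray(labels).copy()
    history: list[list[int]] = []
    while True:
        module_ids = [int(m) for m in np.unique(labels) if m != 0]
        if len(module_ids) < 2:
            break
        ME, _, ids = eigenproteins(X, labels)
        diss = 1.0 - pearson_matrix(ME)
        np.fill_diagonal(diss, 0.0)
        Z = cluster_tree(diss)
        groups = fcluster(Z, t=merge_cut_height, criterion="distance")
        if len(np.unique(groups)) == len(ids):
            break
        new_labels = np.zeros_like(labels)
        for g in np.unique(groups):
            merged_ids = [ids[i] for i in np.flatnonzero(groups == g)]
            if len(merged_ids) > 1:
                history.append(sorted(merged_ids))
            for mid in merged_ids:
                new_labels[labels == mid] = int(g)
        labels = new_labels
    return relabel_by_size(labels), history


def reassign(
    X: np.ndarray, labels: np.ndarray, reassign_threshold: float = 0.05
) -> tuple[np.ndarray, list[dict]]:
    """Single-pass kME-based reassignment of assigned proteins.

    A protein moves from its module ``m`` to ``m'`` when ``kME(p, m') >
    kME(p, m)`` and the ``kME(p, m')`` p-value is below the threshold.  With
    threshold 0 the operation is the identity.  Returns labels (renumbered)
    and a log of moves.
    """
    labels = np.asarray(labels).copy()
    moves: list[dict] = []
    if reassign_threshold <= 0:
        return relabel_by_size(labels), moves
    ME, _, ids = eigenproteins(X, labels)
    if not ids:
        return labels, moves
    K, P = kme(X, ME)
    col_of = {m: i for i, m in enumerate(ids)}
    for p_idx in np.flatnonzero(labels != 0):
        own = int(labels[p_idx])
        best_col = int(np.argmax(K[p_idx]))
        best = ids[best_col]
        if best != own and K[p_idx, best_col] > K[p_idx, col_of[own]] \
                and P[p_idx, best_col] < reassign_threshold:
            moves.append(
                {
                    "protein_index": int(p_idx),
                    "from": own,
                    "to": best,
                    "kme_from": float(K[p_idx, col_of[own]]),
                    "kme_to": float(K[p_idx, best_col]),
                }
            )
            labels[p_idx] = best
    if moves:
        logger.info("reassignment moved %d protein(s)", len(moves))
    return relabel_by_size(labels), moves


def kme_sweep(
    X: np.ndarray,
    labels: np.ndarray,
    significance: float = 0.05,
    min_module_size: int = 25,
    max_iter: int = 3,
) -> np.ndarray:
    """Iterative kME-based membership refinement.

    With module cores fixed by the tree cut, each protein is (re)assigned to
    the module whose eigenprotein it correlates with most strongly, provided
    that correlation is significant at ``significance``; otherwise it is
    unassigned.  Eigenproteins are recomputed and the sweep repeats until
    stable (at most ``max_iter`` rounds).  Modules driven below
    ``min_module_size`` dissolve.  The correlation-scale test is better
    powered than topological overlap at small sample sizes, which is why the
    final membership decision is made here rather than in the PAM stage.
    """
    labels = np.asarray(labels).copy()
    if significance <= 0:
        return labels
    for _ in range(max_iter):
        ME, _, ids = eigenproteins(X, labels)
        if not ids:
            break
        K, P = kme(X, ME)
        best = np.argmax(K, axis=1)
        rows = np.arange(len(labels))
        # picking the best of k eigenproteins is a k-fold selection, so the
        # membership test is Bonferroni-gated across the candidate modules
        new = np.where(
            P[rows, best] < significance / len(ids), np.asarray(ids)[best], 0
        ).astype(int)
        for m in ids:
            if 0 < (new == m).sum() < min_module_size:
                new[new == m] = 0
        if np.array_equal(new, labels):
            break
        labels = new
    return relabel_by_size(labels)


def map_missing(
    profiles: np.ndarray,
    masks: np.ndarray,
    ME: np.ndarray,
    module_ids: list[int],
    min_kme: float | None = None,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Assign half-missing proteins to the best-correlated eigenprotein.

    For each profile, bicor is computed against every eigenprotein restricted
    to the protein's quantified (cognate) samples; the top correlation wins.
    Assignments carry the correlation, the number of samples used, and a
    reduced-confidence flag (n below the full design).  ``min_kme`` optionally
    refuses assignments whose best correlation falls below it.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    masks = np.atleast_2d(np.asarray(masks, dtype=bool))
    n_full = profiles.shape[1]
    rows = []
    for i in range(profiles.shape[0]):
        obs = masks[i] & ~np.isnan(profiles[i])
        n = int(obs.sum())
        if n < min_obs:
            logger.warning("half-missing protein %d: only %d cognate samples; unassigned", i, n)
            rows.append({"module": 0, "kme": np.nan, "n": n,
                         "reduced_confidence": True, "negative_best": False})
            continue
        x = profiles[i, obs]
        cors = np.array([bicor(x, me[obs]) for me in ME])
        best = int(np.argmax(cors))
        r = float(cors[best])
        module = int(module_ids[best])
        if min_kme is not None and r < min_kme:
            module = 0
        rows.append(
            {
                "module": module,
                "kme": r,
                "n": n,
                "reduced_confidence": n < n_full,
                "negative_best": r < 0,
            }
        )
    return pd.DataFrame(rows)
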