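"""Pearson and biweight midcorrelation (bicor).

bicor is an outlier-robust correlation built from Tukey biweights around the
median: with ``u_i = (x_i - med(x)) / (9 * mad(x))`` and weights
``w_i = (1 - u_i^2)^2 * I(|u_i| < 1)``,

    r = sum(w_x (x - med) * w_y (y - med))
        / sqrt( sum[(w_x (x - med))^2] * sum[(w_y (y - med))^2] )

A vector with ``mad = 0`` (no spread around the median) falls back to plain
Pearson weighting for that vector, with a log message — the conventional
robust-correlation behaviour.  Binary traits always use the non-robust side
(their mad is degenerate by construction).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

logger = logging.getLogger("protnet")


def _biweight_rows(X: np.ndarray, robust: bool = True) -> np.ndarray:
    """Per-row biweight-centered, unit-norm vectors; Pearson fallback rows where mad=0."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return _biweight_rows(X[None, :], robust=robust)[0]
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0) | (not robust)
    if robust and np.any(mad[:, 0] == 0):
        logger.debug("bicor: %d vector(s) with mad=0, Pearson fallback", int((mad[:, 0] == 0).sum()))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        u = (X - med) / (9.0 * mad)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        a = np.nan_to_num(w * (X - med))
    # Pearson fallback: mean-centered, unit weights
    a[fallback] = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
    norm = np.sqrt((a**2).sum(axis=1, keepdims=True))
    zero = norm[:, 0] == 0
    if np.any(zero):
        norm[zero] = 1.0
        a[zero] = np.nan  # constant vector: correlation undefined
    return a / norm


def bicor(x: np.ndarray, y: np.ndarray, robust_x: bool = True, robust_y: bool = True) -> float:
    """Biweight midcorrelation between two vectors (complete observations)."""
    ax = _biweight_rows(np.asarray(x, dtype=float), robust=robust_x)
    ay = _biweight_rows(np.asarray(y, dtype=float), robust=robust_y)
    return float(np.clip(ax @ ay, -1.0, 1.0))


def bicor_matrix(X: np.ndarray, robust: bool = True) -> np.ndarray:
    """All pairwise bicor between rows of ``X`` (complete data)."""
    A = _biweight_rows(X, robust=robust)
    R = np.clip(A @ A.T, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return R


def pearson_matrix(X: np.ndarray) -> np.ndarray:
    """All pairwise Pearson correlation between rows of ``X``."""
    R = np.clip(np.corrcoef(X), -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return R


def pairwise_complete_corr(
    x: np.ndarray,
    y: np.ndarray,
    x_mask: np.ndarray | None = None,
    y_mask: np.ndarray | None = None,
    method: str = "bicor",
    min_obs: int = 3,
) -> tuple[float, int]:
    """Correlation over the samples where both vectors are quantified.

    Returns ``(r, n_used)``; ``r`` is NaN when fewer than ``min_obs`` samples
    overlap or either restricted vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if x_mask is not None:
        keep &= np.asarray(x_mask, dtype=bool)
    if y_mask is not None:
        keep &= np.asarray(y_mask, dtype=bool)
    n = int(keep.sum())
    if n < min_obs:
        return float("nan"), n
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), n
    if method == "bicor":
        return bicor(xs, ys), n
    if method == "pearson":
        return float(np.clip(np.corrcoef(xs, ys)[0, 1], -1.0, 1.0)), n
    raise ValueError(f"unknown method {method!r}")


def corr_pvalue(r: np.ndarray | float, n: int | np.ndarray) -> np.ndarray | float:
    """Two-sided Student-t p-value for a correlation: t = r*sqrt((n-2)/(1-r^2))."""
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_arr * np.sqrt((n_arr - 2.0) / np.clip(1.0 - r_arr**2, 0.0, None))
    p = np.where(
        np.isnan(r_arr),
        np.nan,
        np.where(np.isclose(np.abs(r_arr), 1.0), 0.0, 2.0 * stats.t.sf(np.abs(t), n_arr - 2.0)),
    )
    return float(p) if np.isscalar(r) or np.ndim(r) == 0 else p


def correlate(matrix, method: str = "pearson", pairwise_complete: bool = False) -> np.ndarray:
    """Protein-protein correlation matrix of an :class:`AbundanceMatrix`.

    With ``pairwise_complete`` each pair uses only its jointly quantified
    samples (needed when half-missing proteins are present); otherwise the
    matrix must be complete.
    """
    X = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, dtype=float)
    if not pairwise_complete:
        if np.isnan(X).any():
            raise ValueError("matrix has missing cells; use pairwise_complete=True")
        return bicor_matrix(X) if method == "bicor" else pearson_matrix(X)
    n = X.shape[0]
    R = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r, _ = pairwise_complete_corr(X[i], X[j], method=method)
            R[i, j] = R[j, i] = r
    return R
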