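"""Soft-threshold adjacency and the topological overlap matrix (TOM).

The adjacency converts correlation to connection strength without a hard
cutoff: ``a_ij = |r_ij|^beta`` (unsigned) or ``((1+r_ij)/2)^beta`` (signed).
TOM then rewards shared neighbourhoods:

    omega_ij = (L_ij + a_ij) / (f(k_i, k_j) + 1 - a_ij),   i != j

with ``L_ij = sum_u a_iu a_uj``, ``k_i = sum_u a_iu`` and ``f`` either
``min`` (the classical denominator) or ``mean``.  ``omega_ii = 1`` by
convention, and clustering uses the dissimilarity ``1 - omega``.
"""

from __future__ import annotations

import numpy as np


def adjacency(corr: np.ndarray, beta: int = 29, network_type: str = "unsigned") -> np.ndarray:
    """Soft-threshold adjacency with zero diagonal (for downstream sums)."""
    corr = np.asarray(corr, dtype=float)
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if network_type == "unsigned":
        A = np.abs(corr) ** beta
    elif network_type == "signed":
        A = ((1.0 + corr) / 2.0) ** beta
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(A, 0.0)
    return A


def topological_overlap(A: np.ndarray, denom: str = "mean") -> np.ndarray:
    """TOM similarity from a symmetric adjacency with entries in [0, 1]."""
    A = np.asarray(A, dtype=float)
    if A.min() < 0 or A.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    if denom == "min":
        F = np.minimum.outer(k, k)
    elif denom == "mean":
        F = (k[:, None] + k[None, :]) / 2.0
    else:
        raise ValueError(f"unknown denom {denom!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (L + A) / (F + 1.0 - A)
    omega = np.nan_to_num(omega, nan=0.0)
    np.fill_diagonal(omega, 1.0)
    return omega
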