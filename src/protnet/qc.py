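"""Sample network connectivity QC.

Before any analysis, samples are screened for outliers by their standardized
network connectivity: over the complete proteins, the inter-sample Pearson
correlation matrix C gives each sample a connectivity k_i = sum_{j != i} C_ij,
standardized to Z_k.  Samples with |Z_k| beyond a threshold (default 3 SD)
are flagged.  Flagged samples are reported, not silently removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .types import AbundanceMatrix


class SampleConnectivityQC(BaseEstimator):
    """Connectivity-based sample outlier detector.

    ``X`` is ``(n_proteins, n_samples)`` — columns are the objects screened.

    Attributes
    ----------
    connectivity_ : per-sample k_i
    z_k_ : standardized connectivity
    outlier_ : boolean flags, |Z_k| > threshold_sd
    """

    def __init__(self, threshold_sd: float = 3.0):
        self.threshold_sd = threshold_sd

    def fit(self, X: np.ndarray, y=None) -> "SampleConnectivityQC":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 3:
            raise ValueError("need at least 3 samples (columns)")
        if np.isnan(X).any():
            raise ValueError("QC runs on complete proteins only")
        sds = X.std(axis=0)
        if np.any(sds == 0):
            bad = np.flatnonzero(sds == 0)
            raise ValueError(f"zero-variance sample column(s) at index {bad.tolist()}")
        C = np.corrcoef(X.T)
        k = C.sum(axis=1) - np.diag(C)
        sd = k.std(ddof=0)
        # affine-identical samples have numerically constant connectivity
        degenerate = sd <= 1e-10 * max(1.0, float(np.abs(k).max()))
        z = np.zeros_like(k) if degenerate else (k - k.mean()) / sd
        self.connectivity_ = k
        self.z_k_ = z
        self.outlier_ = np.abs(z) > self.threshold_sd
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray:
        """sklearn outlier convention: -1 for outliers, +1 for inliers (fitted samples)."""
        check_is_fitted(self, "outlier_")
        return np.where(self.outlier_, -1, 1)


def sample_connectivity(matrix: AbundanceMatrix, threshold_sd: float = 3.0) -> dict:
    """QC report for an :class:`AbundanceMatrix` (complete proteins only)."""
    complete = matrix.complete_index()
    qc = SampleConnectivityQC(threshold_sd=threshold_sd).fit(matrix.values[complete])
    report = {
        "threshold_sd": threshold_sd,
        "n_proteins_used": int(complete.size),
        "samples": {
            s.sample_id: {
                "connectivity": float(qc.connectivity_[i]),
                "z_k": float(qc.z_k_[i]),
                "outlier": bool(qc.outlier_[i]),
            }
            for i, s in enumerate(matrix.samples)
        },
        "n_outliers": int(qc.outlier_.sum()),
    }
    return report


def qc_frame(report: dict) -> pd.DataFrame:
    rows = [
        {"sample_id": sid, **vals} for sid, vals in report["samples"].items()
    ]
    return pd.DataFrame(rows)
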