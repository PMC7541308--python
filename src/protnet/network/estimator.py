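"""Weighted co-expression module detection as a scikit-learn estimator."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from ._correlation import bicor_matrix, pearson_matrix
from ._modules import (
    eigenproteins,
    kme,
    kme_sweep,
    merge_modules,
    reassign,
    relabel_by_size,
)
from ._tom import adjacency, topological_overlap
from ._treecut import cluster_tree, dynamic_hybrid_cut


class CoexpressionModules(ClusterMixin, BaseEstimator):
    """Detect co-expression modules from a complete log2 abundance matrix.

    The pipeline is: pairwise correlation -> soft-threshold adjacency
    (power ``beta``) -> topological overlap -> average-linkage clustering of
    ``1 - TOM`` -> dynamic hybrid tree cut -> eigenprotein merge -> kME-based
    reassignment.  Defaults reproduce the published analysis settings
    (unsigned network, beta 29, TOM mean denominator, deepSplit 4, minimum
    module size 25, merge cut 0.07, PAM stage, reassignment p < 0.05).

    Unlike most scikit-learn clusterers this estimator clusters the *rows*
    of ``X`` as features-of-interest: ``X`` is ``(n_proteins, n_samples)``.

    Attributes
    ----------
    labels_ : ndarray of shape (n_proteins,)
        Module labels; 1..k ordered by decreasing size, 0 = unassigned.
    eigenproteins_ : ndarray of shape (n_modules, n_samples)
        Unit-norm first principal components per module.
    var_explained_ : ndarray of shape (n_modules,)
    kme_ : ndarray of shape (n_proteins, n_modules)
        Pearson correlation of each protein with each eigenprotein.
    kme_pvalues_ : ndarray, two-sided Student-t p-values for ``kme_``.
    module_ids_ : list of module ids matching eigenprotein rows.
    dendrogram_ : scipy linkage matrix over proteins.
    tom_ : topological overlap matrix (kept for inspection).
    merge_history_ : list of merged module-id groups.
    reassignment_log_ : list of dicts describing kME moves.
    """

    def __init__(
        self,
        beta: int = 29,
        network_type: str = "unsigned",
        corr_method: str = "pearson",
        tom_denom: str = "mean",
        deep_split: int = 4,
        min_module_size: int = 25,
        merge_cut_height: float = 0.07,
        pam_stage: bool = True,
        reassign_threshold: float = 0.05,
    ):
        self.beta = beta
        self.network_type = network_type
        self.corr_method = corr_method
        self.tom_denom = tom_denom
        self.deep_split = deep_split
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        self.pam_stage = pam_stage
        self.reassign_threshold = reassign_threshold

    def fit(self, X: np.ndarray, y=None) -> "CoexpressionModules":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 3:
            raise ValueError("X must be (n_proteins >= 3, n_samples >= 3)")
        if np.isnan(X).any():
            raise ValueError("X must be complete; map half-missing proteins separately")
        R = bicor_matrix(X) if self.corr_method == "bicor" else pearson_matrix(X)
        A = adjacency(R, beta=self.beta, network_type=self.network_type)
        self.tom_ = topological_overlap(A, denom=self.tom_denom)
        diss = 1.0 - self.tom_
        np.fill_diagonal(diss, 0.0)
        self.dendrogram_ = cluster_tree(diss)
        raw = dynamic_hybrid_cut(
            self.dendrogram_,
            diss,
            deep_split=self.deep_split,
            min_module_size=self.min_module_size,
            pam_stage=self.pam_stage,
        )
        self.raw_labels_ = relabel_by_size(raw)
        labels, self.merge_history_ = merge_modules(X, self.raw_labels_, self.merge_cut_height)
        labels, self.reassignment_log_ = reassign(X, labels, self.reassign_threshold)
        labels = kme_sweep(
            X, labels,
            significance=self.reassign_threshold,
            min_module_size=self.min_module_size,
        )
        self.labels_ = labels
        self.eigenproteins_, self.var_explained_, self.module_ids_ = eigenproteins(X, labels)
        if self.module_ids_:
            self.kme_, self.kme_pvalues_ = kme(X, self.eigenproteins_)
        else:
            self.kme_ = np.zeros((X.shape[0], 0))
            self.kme_pvalues_ = np.zeros((X.shape[0], 0))
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def module_set(self, proteins: list[str], sample_ids: list[str]) -> dict:
        """Result bundle keyed for report writing."""
        check_is_fitted(self, "labels_")
        names = [f"M{m}" for m in self.module_ids_]
        return {
            "labels": pd.Series(self.labels_, index=proteins, name="module"),
            "eigenproteins": pd.DataFrame(self.eigenproteins_, index=names, columns=sample_ids),
            "var_explained": pd.Series(self.var_explained_, index=names),
            "kme": pd.DataFrame(self.kme_, index=proteins, columns=names),
            "kme_pvalues": pd.DataFrame(self.kme_pvalues_, index=proteins, columns=names),
            "merge_history": self.merge_history_,
            "reassignment_log": self.reassignment_log_,
        }
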