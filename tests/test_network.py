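import numpy as np
import pytest
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from protnet.network import (
    CoexpressionModules,
    adjacency,
    bicor,
    bicor_matrix,
    cluster_tree,
    corr_pvalue,
    dynamic_hybrid_cut,
    eigenproteins,
    kme,
    map_missing,
    merge_modules,
    pairwise_complete_corr,
    pearson_matrix,
    reassign,
    relabel_by_size,
    topological_overlap,
)

from _oracles import average_linkage_naive, bicor_direct, tom_triple_loop


def random_adjacency(rng, n=20):
    A = rng.random((n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=30)
        assert bicor(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_reversed_sequence_is_minus_one(self):
        assert bicor([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)

    def test_outlier_vector_matches_direct_formula_evaluation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert bicor(x, y) == pytest.approx(bicor_direct(x, y), abs=1e-12)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 16))
            r = bicor(x, y)
            assert -1.0 <= r <= 1.0
            assert r == pytest.approx(bicor(y, x), abs=1e-14)

    def test_mad_zero_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 9.0])  # mad = 0
        y = np.array([0.2, 0.4, 0.3, 0.1, 5.0])
        r = bicor(x, y, robust_y=False)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_matrix_agrees_with_pairwise(self, rng):
        X = rng.normal(size=(6, 16))
        R = bicor_matrix(X)
        for i in range(6):
            for j in range(6):
                assert R[i, j] == pytest.approx(bicor(X[i], X[j]), abs=1e-12)

    def test_pairwise_complete_uses_overlap_only(self, rng):
        x = rng.normal(size=16)
        y = 2 * x + rng.normal(0, 0.01, 16)
        x_obs = x.copy()
        x_obs[8:] = np.nan
        r, n = pairwise_complete_corr(x_obs, y, method="pearson")
        assert n == 8
        assert r == pytest.approx(np.corrcoef(x[:8], y[:8])[0, 1], abs=1e-12)

    def test_too_few_overlapping_observations(self):
        x = np.array([1.0, 2.0, np.nan, np.nan, np.nan])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, n = pairwise_complete_corr(x, y)
        assert n == 2 and np.isnan(r)

    def test_corr_pvalue_against_t_distribution(self):
        # r = 0.8, n = 16: t = 0.8*sqrt(14/0.36)
        t = 0.8 * np.sqrt(14 / 0.36)
        expected = 2 * stats.t.sf(t, 14)
        assert corr_pvalue(0.8, 16) == pytest.approx(expected, rel=1e-10)
        assert corr_pvalue(0.0, 16) == pytest.approx(1.0)


class TestAdjacency:
    def test_known_values(self):
        R = np.array([[1.0, 0.5, -1.0], [0.5, 1.0, 1.0], [-1.0, 1.0, 1.0]])
        A = adjacency(R, beta=2, network_type="unsigned")
        assert A[0, 1] == pytest.approx(0.25)
        assert A[0, 2] == pytest.approx(1.0)
        assert A[1, 2] == pytest.approx(1.0)
        assert np.all(np.diag(A) == 0)
        S = adjacency(R, beta=5, network_type="signed")
        assert S[0, 2] == pytest.approx(0.0)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            adjacency(np.eye(2), beta=0)


class TestTopologicalOverlap:
    def test_empty_graph(self):
        omega = topological_overlap(np.zeros((4, 4)))
        assert np.all(omega == np.eye(4))

    def test_complete_graph_closed_form(self):
        n = 6
        A = np.ones((n, n)) - np.eye(n)
        for denom in ("min", "mean"):
            omega = topological_overlap(A, denom)
            np.testing.assert_allclose(omega, 1.0, atol=1e-12)

    def test_three_node_hand_computation(self):
        A = np.array([[0, 0.8, 0.6], [0.8, 0, 0.4], [0.6, 0.4, 0]])
        omega = topological_overlap(A, "mean")
        k1, k2 = 1.4, 1.2
        expected = (0.6 * 0.4 + 0.8) / ((k1 + k2) / 2 + 1 - 0.8)
        assert omega[0, 1] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("denom", ["min", "mean"])
    def test_matches_triple_loop_oracle(self, denom, rng):
        for _ in range(25):
            A = random_adjacency(rng)
            np.testing.assert_allclose(
                topological_overlap(A, denom), tom_triple_loop(A, denom), atol=1e-12
            )

    @pytest.mark.parametrize("denom", ["min", "mean"])
    def test_bounded_by_one(self, denom, rng):
        for _ in range(25):
            omega = topological_overlap(random_adjacency(rng), denom)
            assert omega.max() <= 1.0 + 1e-12

    def test_out_of_range_entries_fatal(self):
        A = np.full((3, 3), 1.5)
        np.fill_diagonal(A, 0)
        with pytest.raises(ValueError):
            topological_overlap(A)


class TestClusterTree:
    def test_two_separated_blocks(self):
        D = np.ones((8, 8))
        D[:4, :4] = 0.0
        D[4:, 4:] = 0.0
        np.fill_diagonal(D, 0.0)
        Z = cluster_tree(D)
        assert Z[-1, 2] == pytest.approx(1.0)
        assert np.all(Z[:-1, 2] == 0.0)

    def test_three_point_ordering(self):
        D = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        Z = cluster_tree(D)
        assert Z[0, 2] == pytest.approx(0.1)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[1, 2] == pytest.approx(0.9)

    def test_matches_naive_average_linkage(self, rng):
        D = rng.random((15, 15))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        Z = cluster_tree(D)
        ref = average_linkage_naive(D)
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(m[2] for m in ref), atol=1e-12)

    def test_nan_fatal(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            cluster_tree(D)


def block_dissimilarity(sizes, rng, within=0.05, between=0.95, noise=0.02):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    D = np.full((n, n), between) + rng.normal(0, noise, (n, n))
    same = labels[:, None] == labels[None, :]
    D[same] = within + rng.normal(0, noise, same.sum())
    D = np.clip((D + D.T) / 2, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return D, labels


class TestDynamicHybridCut:
    def test_two_clean_blocks(self, rng):
        D, truth = block_dissimilarity([30, 30], rng)
        Z = cluster_tree(D)
        labels = dynamic_hybrid_cut(Z, D, min_module_size=25)
        assert len(set(labels)) == 2
        assert 0 not in labels
        # one-to-one correspondence with the planted blocks
        for b in (0, 1):
            assert len(set(labels[truth == b])) == 1

    def test_undersized_block_dissolved(self, rng):
        # a single tight block below the minimum size, plus scattered noise
        n_block, n_noise = 20, 40
        n = n_block + n_noise
        D = rng.uniform(0.7, 1.0, (n, n))
        D[:n_block, :n_block] = rng.uniform(0.0, 0.05, (n_block, n_block))
        D = np.clip((D + D.T) / 2, 0, 1)
        np.fill_diagonal(D, 0.0)
        labels = dynamic_hybrid_cut(cluster_tree(D), D, min_module_size=25)
        assert np.all(labels[:n_block] == 0)

    def test_min_size_larger_than_n_warns_all_unassigned(self, rng):
        D, _ = block_dissimilarity([10], rng)
        with pytest.warns(UserWarning):
            labels = dynamic_hybrid_cut(cluster_tree(D), D, min_module_size=99)
        assert np.all(labels == 0)

    def test_labels_ordered_by_size(self, rng):
        D, _ = block_dissimilarity([40, 30, 28], rng)
        labels = dynamic_hybrid_cut(cluster_tree(D), D, min_module_size=25)
        sizes = np.bincount(labels)[1:]
        assert len(sizes) == 3
        assert list(sizes) == sorted(sizes, reverse=True)


class TestEigenproteins:
    def test_identical_profiles_rank_one(self, rng):
        profile = rng.normal(size=16)
        X = np.vstack([3 * profile + 1, 0.5 * profile - 2, profile])
        ME, var_exp, ids = eigenproteins(X, np.array([1, 1, 1]))
        assert ids == [1]
        assert var_exp[0] == pytest.approx(1.0)
        r = np.corrcoef(ME[0], profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)  # oriented with the mean profile

    def test_two_anticorrelated_profiles(self, rng):
        profile = rng.normal(size=16)
        X = np.vstack([profile, -profile])
        ME, var_exp, _ = eigenproteins(X, np.array([1, 1]))
        assert var_exp[0] == pytest.approx(1.0)
        assert abs(np.corrcoef(ME[0], profile)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_pca_optimality_over_random_summaries(self, rng):
        X = rng.normal(size=(12, 16)) + rng.normal(size=16) * 1.5
        labels = np.ones(12, dtype=int)
        ME, var_exp, _ = eigenproteins(X, labels)
        Xz = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        total = (Xz**2).sum()
        for _ in range(100):
            v = rng.normal(size=16)
            v /= np.linalg.norm(v)
            explained = ((Xz @ v) ** 2).sum() / total
            assert var_exp[0] >= explained - 1e-12
        # and it equals the mean squared kME up to protein standardization
        K, _ = kme(X, ME)
        assert var_exp[0] == pytest.approx((K[:, 0] ** 2).mean(), abs=1e-10)


class TestKme:
    def test_protein_equal_to_eigenprotein(self, rng):
        me = rng.normal(size=16)
        K, P = kme(me[None, :], me[None, :])
        assert K[0, 0] == pytest.approx(1.0)
        assert P[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_profile(self):
        me = np.tile([1.0, -1.0], 8)
        x = np.tile([1.0, 1.0, -1.0, -1.0], 4)
        K, P = kme(x[None, :], me[None, :])
        assert K[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert P[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_pvalue_from_t_oracle(self, rng):
        me = rng.normal(size=16)
        x = 0.9 * me + rng.normal(0, 0.4, 16)
        K, P = kme(x[None, :], me[None, :])
        r = K[0, 0]
        t = r * np.sqrt(14 / (1 - r**2))
        assert P[0, 0] == pytest.approx(2 * stats.t.sf(abs(t), 14), rel=1e-8)


class TestMergeModules:
    def _two_module_matrix(self, rng, correlation):
        # construct eigenprofiles with *exactly* the requested sample correlation
        e1 = rng.normal(size=16)
        e1 = (e1 - e1.mean()) / e1.std()
        noise = rng.normal(size=16)
        noise = noise - noise.mean()
        noise -= (noise @ e1) / (e1 @ e1) * e1
        noise /= noise.std()
        e2 = correlation * e1 + np.sqrt(1 - correlation**2) * noise
        X1 = np.vstack([e1 * rng.normal(1, 0.05) for _ in range(10)])
        X2 = np.vstack([e2 * rng.normal(1, 0.05) for _ in range(10)])
        return np.vstack([X1, X2]), np.array([1] * 10 + [2] * 10)

    def test_identical_eigenproteins_merged(self, rng):
        X, labels = self._two_module_matrix(rng, 1.0)
        merged, history = merge_modules(X, labels, 0.07)
        assert len(np.unique(merged)) == 1
        assert history

    def test_threshold_arithmetic(self, rng):
        X_no, labels = self._two_module_matrix(rng, 0.90)  # diss 0.10 > 0.07
        merged_no, _ = merge_modules(X_no, labels, 0.07)
        assert len(np.unique(merged_no)) == 2
        X_yes, labels = self._two_module_matrix(rng, 0.95)  # diss 0.05 < 0.07
        merged_yes, _ = merge_modules(X_yes, labels, 0.07)
        assert len(np.unique(merged_yes)) == 1


class TestReassign:
    def test_dominant_foreign_kme_reassigned(self, rng):
        e1, e2 = rng.normal(size=(2, 16))
        X = np.vstack(
            [e1 + rng.normal(0, 0.1, 16) for _ in range(5)]
            + [e2 + rng.normal(0, 0.1, 16) for _ in range(5)]
        )
        labels = np.array([1] * 5 + [2] * 4 + [1])  # last protein mislabeled
        new, moves = reassign(X, labels, 0.05)
        assert len(moves) == 1
        # after renumbering, the mislabeled protein sits with its real peers
        assert new[9] == new[5]

    def test_best_in_own_module_unchanged(self, rng):
        e1, e2 = rng.normal(size=(2, 16))
        X = np.vstack(
            [e1 + rng.normal(0, 0.1, 16) for _ in range(5)]
            + [e2 + rng.normal(0, 0.1, 16) for _ in range(5)]
        )
        labels = np.array([1] * 5 + [2] * 5)
        new, moves = reassign(X, labels, 0.05)
        assert moves == []
        np.testing.assert_array_equal(relabel_by_size(labels), new)

    def test_threshold_zero_is_identity(self, rng):
        X = rng.normal(size=(10, 16))
        labels = np.array([1] * 5 + [2] * 5)
        new, moves = reassign(X, labels, 0.0)
        assert moves == []
        np.testing.assert_array_equal(new, relabel_by_size(labels))


class TestMapMissing:
    def test_profile_equal_to_eigenprotein(self, rng):
        ME = rng.normal(size=(3, 16))
        profile = ME[2].copy()
        mask = np.zeros(16, dtype=bool)
        mask[:8] = True
        out = map_missing(profile, mask, ME, [1, 2, 3])
        assert out.loc[0, "module"] == 3
        assert out.loc[0, "kme"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc[0, "n"] == 8
        assert bool(out.loc[0, "reduced_confidence"])

    def test_anticorrelated_profile_still_assigned_with_flag(self, rng):
        # two positively correlated eigenproteins; the profile opposes both
        ME = np.vstack([np.linspace(0, 1, 16), np.linspace(0, 1, 16) ** 2])
        profile = -ME[0] - ME[1]
        mask = np.ones(16, dtype=bool)
        out = map_missing(profile, mask, ME, [1, 2])
        assert out.loc[0, "module"] in (1, 2)
        assert bool(out.loc[0, "negative_best"])
        # with a minimum-kME option the assignment is refused instead
        strict = map_missing(profile, mask, ME, [1, 2], min_kme=0.0)
        assert strict.loc[0, "module"] == 0

    def test_too_few_cognate_samples_unassigned(self, rng):
        ME = rng.normal(size=(2, 16))
        mask = np.zeros(16, dtype=bool)
        mask[:2] = True
        out = map_missing(ME[0], mask, ME, [1, 2])
        assert out.loc[0, "module"] == 0


class TestCoexpressionModulesEstimator:
    def test_sklearn_params_round_trip(self):
        est = CoexpressionModules(beta=12, deep_split=2)
        params = est.get_params()
        assert params["beta"] == 12
        clone = CoexpressionModules().set_params(**params)
        assert clone.get_params() == params

    def test_determinism(self, default_sim):
        matrix, _, _ = default_sim
        X = matrix.values[matrix.complete_index()]
        m1 = CoexpressionModules().fit(X)
        m2 = CoexpressionModules().fit(X)
        np.testing.assert_array_equal(m1.labels_, m2.labels_)
        np.testing.assert_allclose(m1.eigenproteins_, m2.eigenproteins_, atol=1e-12)

    def test_protein_order_permutation_stability(self, default_sim):
        matrix, _, _ = default_sim
        X = matrix.values[matrix.complete_index()]
        rng = np.random.default_rng(0)
        perm = rng.permutation(X.shape[0])
        m1 = CoexpressionModules().fit(X)
        m2 = CoexpressionModules().fit(X[perm])
        sizes1 = sorted(np.bincount(m1.labels_)[1:], reverse=True)
        sizes2 = sorted(np.bincount(m2.labels_)[1:], reverse=True)
        assert len(m1.module_ids_) == len(m2.module_ids_)
        assert np.array_equal(sizes1, sizes2) or (
            # permutation may flip a handful of borderline memberships
            np.abs(np.array(sizes1) - np.array(sizes2)).sum() <= 4
        )

    def test_incomplete_input_rejected(self):
        X = np.ones((5, 6))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            CoexpressionModules().fit(X)
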