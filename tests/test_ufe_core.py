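import numpy as np
import pytest
from scipy import stats

from pcufe import (
    ExpressionMatrix,
    SampleAnnotation,
    UFEConfig,
    benjamini_hochberg,
    compute_loadings,
    compute_pca,
    normalize_samples,
    recompute_stage2,
    run_ufe,
    score_features,
    select_components,
    select_features,
    test_component_association as associate_components,
)
from pcufe.exceptions import DecompositionError, EmptySelectionError
from pcufe.ufe_core import ComponentAssociation

from conftest import random_normalized_matrix


def brute_force_bh(p):
    """Independent step-up oracle: direct definition, O(m^2)-style."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos in range(m):
        k = rank_pos + 1
        candidates = [p[order[r]] * m / (r + 1) for r in range(rank_pos, m)]
        adj[order[rank_pos]] = min(1.0, min(candidates))
    return adj


class TestComputePCA:
    def test_gram_eigendecomposition_oracle(self, rng):
        m = random_normalized_matrix(rng, n=10, m=4)
        pcd = compute_pca(m)
        gram = m.values @ m.values.T
        w, v = np.linalg.eigh(gram)
        w, v = w[::-1], v[:, ::-1]
        for l in range(pcd.n_components):
            np.testing.assert_allclose(pcd.eigenvalues[l], w[l], atol=1e-8)
            dot = abs(v[:, l] @ pcd.scores[:, l])
            np.testing.assert_allclose(dot, 1.0, atol=1e-8)

    def test_scores_orthonormal(self, small_normalized):
        pcd = compute_pca(small_normalized)
        gram = pcd.scores.T @ pcd.scores
        np.testing.assert_allclose(gram, np.eye(pcd.n_components), atol=1e-8)

    def test_eigenvalues_nonincreasing(self, small_normalized):
        pcd = compute_pca(small_normalized)
        assert np.all(np.diff(pcd.eigenvalues) <= 1e-12)

    def test_energy_identity(self, rng):
        m = random_normalized_matrix(rng, n=30, m=8)
        pcd = compute_pca(m)
        np.testing.assert_allclose(
            pcd.eigenvalues.sum(), 30 * 8, rtol=1e-6
        )

    def test_unnormalized_rejected(self, rng):
        raw = ExpressionMatrix(
            feature_ids=[f"f{i}" for i in range(5)],
            sample_ids=["a", "b", "c"],
            values=rng.uniform(1, 10, size=(5, 3)),
        )
        with pytest.raises(DecompositionError, match="normaliz"):
            compute_pca(raw)

    def test_sign_convention(self, small_normalized):
        pcd = compute_pca(small_normalized)
        for l in range(pcd.n_components):
            col = pcd.scores[:, l]
            assert col[np.argmax(np.abs(col))] > 0

    def test_loading_identity_and_sum_sq(self, rng):
        # v_lj = sum_i x_ij u_li and sum_j v_lj^2 = lambda_l
        m = random_normalized_matrix(rng, n=25, m=6)
        pcd = compute_pca(m)
        np.testing.assert_allclose(
            pcd.loadings, pcd.scores.T @ m.values, atol=1e-8
        )
        np.testing.assert_allclose(
            (pcd.loadings**2).sum(axis=1), pcd.eigenvalues, atol=1e-8
        )


class TestComputeLoadings:
    def test_zero_matrix(self):
        m = ExpressionMatrix(
            feature_ids=["f1", "f2", "f3"],
            sample_ids=["a", "b"],
            values=np.zeros((3, 2)),
        )
        v = compute_loadings(m, np.eye(3, 2))
        np.testing.assert_array_equal(v, 0.0)

    def test_svd_oracle(self, rng):
        m = random_normalized_matrix(rng, n=10, m=4)
        u_svd, s, wt = np.linalg.svd(m.values, full_matrices=False)
        v = compute_loadings(m, u_svd)
        expected = s[:, None] * wt
        np.testing.assert_allclose(v, expected, atol=1e-8)

    def test_dimension_mismatch(self, small_normalized, rng):
        with pytest.raises(DecompositionError):
            compute_loadings(small_normalized, rng.normal(size=(7, 2)))


class TestComponentAssociation:
    def test_equal_class_means_p_one(self, balanced_annot):
        v = np.array([[1.0, -1.0, 1.0, -1.0]])
        out = associate_components(v, balanced_annot)
        assert out[0].f_statistic == 0.0
        assert out[0].p_raw == 1.0

    def test_degenerate_separated_p_zero(self, balanced_annot):
        v = np.array([[2.0, 2.0, -2.0, -2.0]])
        with pytest.warns(RuntimeWarning, match="zero within-class"):
            out = associate_components(v, balanced_annot)
        assert out[0].p_raw == 0.0

    def test_t_test_oracle(self, rng):
        # F-test p equals the squared-t two-sample p to 1e-12
        labels = ["A"] * 6 + ["B"] * 6
        annot = SampleAnnotation(
            sample_ids=[f"s{j}" for j in range(12)], class_labels=labels
        )
        v = rng.normal(size=(20, 12))
        out = associate_components(v, annot)
        for l, assoc in enumerate(out):
            t, p = stats.ttest_ind(v[l, :6], v[l, 6:], equal_var=True)
            assert abs(assoc.p_raw - p) < 1e-12
            assert abs(assoc.f_statistic - t**2) < 1e-9

    def test_sum_to_zero_coding(self, balanced_annot):
        v = np.array([[1.0, 3.0, 10.0, 14.0]])
        out = associate_components(v, balanced_annot)
        a = out[0]
        assert a.intercept == pytest.approx(7.0)
        assert a.effects[0] == pytest.approx(-5.0)
        assert a.effects[1] == pytest.approx(5.0)
        assert a.effects[0] + a.effects[1] == pytest.approx(0.0)

    def test_adjusted_ge_raw(self, rng, balanced_annot):
        v = rng.normal(size=(15, 4))
        out = associate_components(v, balanced_annot)
        for a in out:
            assert a.p_adjusted >= a.p_raw - 1e-15


class TestBenjaminiHochberg:
    def test_worked_example(self):
        adjusted = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg(np.array([0.37])), [0.37])

    def test_all_equal(self):
        adjusted = benjamini_hochberg(np.full(7, 0.2))
        np.testing.assert_allclose(adjusted, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([0.1, 1.5]))
        with pytest.raises(ValueError):
            benjamini_hochberg(np.array([-0.1, 0.5]))

    def test_brute_force_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                benjamini_hochberg(p), brute_force_bh(p), atol=1e-12
            )

    def test_statsmodels_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=25)
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)


class TestSelectComponents:
    def _assocs(self, adjusted):
        return [
            ComponentAssociation(
                component=l + 1, intercept=0.0, effects=(0.0, 0.0),
                f_statistic=1.0, p_raw=q, p_adjusted=q,
            )
            for l, q in enumerate(adjusted)
        ]

    def test_threshold(self):
        omega = select_components(self._assocs([0.01, 0.20, 0.04]), alpha=0.05)
        assert omega == [1, 3]

    def test_override_wins(self):
        omega = select_components(self._assocs([0.01, 0.20]), override=[5])
        assert omega == [5]

    def test_empty_raises(self):
        with pytest.raises(EmptySelectionError):
            select_components(self._assocs([0.9, 0.8]), alpha=0.05)

    def test_strict_inequality(self):
        with pytest.raises(EmptySelectionError):
            select_components(self._assocs([0.05]), alpha=0.05)


class TestScoreFeatures:
    def test_zero_scores_give_p_one(self):
        scores = np.zeros((5, 3))
        scores[:, 2] = 1.0  # keep sd positive on unused component
        sd = np.array([1.0, 1.0, 1.0])
        t, p = score_features(scores, sd, [1, 2])
        np.testing.assert_array_equal(t, 0.0)
        np.testing.assert_array_equal(p, 1.0)

    def test_chi2_df1_normal_identity(self):
        # for |omega| = 1, P equals the two-sided standard-normal tail
        zs = np.array([0.5, 1.0, 1.96, 3.0])
        scores = zs[:, None]
        _, p = score_features(scores, np.array([1.0]), [1])
        expected = 2 * stats.norm.sf(np.abs(zs))
        np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_uniform_under_null(self, rng):
        scores = rng.normal(size=(5000, 3))
        _, p = score_features(scores, np.ones(3), [1, 2, 3])
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_sigma_rejected(self):
        with pytest.raises(DecompositionError):
            score_features(np.ones((4, 2)), np.array([0.0, 1.0]), [1])

    def test_empty_omega_rejected(self):
        with pytest.raises(EmptySelectionError):
            score_features(np.ones((4, 2)), np.array([1.0, 1.0]), [])


class TestSelectFeatures:
    def test_threshold(self):
        # raw p chosen so BH-adjusted values stay on the right sides of .01
        p = np.array([0.001, 0.5, 0.003])
        selected, adjusted = select_features(p, alpha=0.01)
        assert list(selected) == [0, 2]

    def test_empty_raises(self):
        with pytest.raises(EmptySelectionError):
            select_features(np.array([0.5, 0.8, 0.9]), alpha=0.01)

    def test_monotone_in_alpha(self, rng):
        p = rng.uniform(size=200) ** 3
        try:
            s1, _ = select_features(p, alpha=0.01)
        except EmptySelectionError:
            s1 = np.array([], dtype=int)
        s2, _ = select_features(p, alpha=0.10)
        assert set(s1).issubset(set(s2))


class TestRecomputeStage2:
    def test_all_features_reproduces_stage1(self, rng, balanced_annot):
        m = random_normalized_matrix(rng, n=12, m=4)
        stage1 = compute_pca(m)
        pcd, _, omega, source = recompute_stage2(
            m, range(12), stage2_omega=[1]
        )
        assert source == "override" and omega == [1]
        for l in range(stage1.n_components):
            np.testing.assert_allclose(
                np.abs(pcd.scores[:, l]), np.abs(stage1.scores[:, l]), atol=1e-8
            )
            np.testing.assert_allclose(
                pcd.eigenvalues[l], stage1.eigenvalues[l], atol=1e-8
            )

    def test_override_honored(self, rng):
        m = random_normalized_matrix(rng, n=12, m=6)
        _, assocs, omega, source = recompute_stage2(
            m, range(6), stage2_omega=[2, 4]
        )
        assert omega == [2, 4]
        assert source == "override"
        assert assocs is None

    def test_contraction_identity(self, rng):
        m = random_normalized_matrix(rng, n=15, m=5)
        selected = [0, 2, 4, 6, 8]
        pcd, _, _, _ = recompute_stage2(m, selected, stage2_omega=[1])
        sub = m.values[selected, :]
        np.testing.assert_allclose(pcd.loadings, pcd.scores.T @ sub, atol=1e-8)

    def test_too_few_features(self, rng):
        m = random_normalized_matrix(rng, n=10, m=4)
        with pytest.raises(DecompositionError):
            recompute_stage2(m, [3], stage2_omega=[1])


class TestRunUFE:
    def test_planted_recovery_strong(self, strong_normalized, strong_cohort):
        res = run_ufe(strong_normalized, strong_cohort.annot, UFEConfig())
        selected = set(res.selected_features)
        recall = len(selected & strong_cohort.truth) / len(strong_cohort.truth)
        fdr = len(selected - strong_cohort.truth) / max(len(selected), 1)
        assert recall >= 0.9
        assert fdr <= 0.2
        assert res.stage2 is not None
        assert res.omega2

    def test_deterministic(self, strong_normalized, strong_cohort):
        r1 = run_ufe(strong_normalized, strong_cohort.annot, UFEConfig())
        r2 = run_ufe(strong_normalized, strong_cohort.annot, UFEConfig())
        np.testing.assert_array_equal(r1.feature_p_raw, r2.feature_p_raw)
        assert r1.omega1 == r2.omega1 and r1.omega2 == r2.omega2
        assert r1.selected_features == r2.selected_features

    def test_misaligned_rejected(self, strong_normalized):
        bad = SampleAnnotation(
            sample_ids=["x1", "x2", "x3", "x4"],
            class_labels=["A", "A", "B", "B"],
        )
        with pytest.raises(DecompositionError, match="align"):
            run_ufe(strong_normalized, bad, UFEConfig())

    def test_omega_overrides_propagate(self, strong_normalized, strong_cohort):
        res = run_ufe(
            strong_normalized,
            strong_cohort.annot,
            UFEConfig(omega1=[2], omega2=[1, 2]),
        )
        assert res.omega1 == [2] and res.omega1_source == "override"
        assert res.omega2 == [1, 2] and res.omega2_source == "override"

    def test_feature_permutation_equivariance(self, strong_normalized, strong_cohort):
        res1 = run_ufe(strong_normalized, strong_cohort.annot, UFEConfig())
        rng = np.random.default_rng(3)
        perm = rng.permutation(strong_normalized.n_features)
        shuffled = strong_normalized.subset_features(perm)
        res2 = run_ufe(shuffled, strong_cohort.annot, UFEConfig())
        assert set(res1.selected_features) == set(res2.selected_features)
        np.testing.assert_allclose(
            res1.feature_p_raw[perm], res2.feature_p_raw, atol=1e-8
        )

    def test_sample_permutation_equivariance(self, strong_normalized, strong_cohort):
        res1 = run_ufe(strong_normalized, strong_cohort.annot, UFEConfig())
        rng = np.random.default_rng(4)
        perm = rng.permutation(strong_normalized.n_samples)
        shuffled = strong_normalized.subset_samples(perm)
        annot = strong_cohort.annot.subset(shuffled.sample_ids)
        res2 = run_ufe(shuffled, annot, UFEConfig())
        assert set(res1.selected_features) == set(res2.selected_features)
        np.testing.assert_allclose(
            res1.stage1.loadings[:, perm], res2.stage1.loadings, atol=1e-6
        )

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            UFEConfig(alpha_features=1.5)
        with pytest.raises(ValueError):
            UFEConfig(omega1=[0])
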