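"""GPA, PCA, Procrustes ANOVA and confidence ellipses."""

import numpy as np
import pytest
from scipy import stats as sps

from equilunge.gpa import (
    align_pair,
    anova_centroid_size,
    centroid_size,
    confidence_ellipse,
    consensus_by_class,
    eigenvalue_variance_stats,
    gpa,
    pca,
    procrustes_anova_shape,
    shape_dimension,
)
from equilunge.landmarks import LungingAid
from equilunge.synthetic import (
    PostureEffectSpec,
    StudyDesign,
    generate_landmark_dataset,
)


def _random_similarity(stack, rng):
    n = len(stack)
    th = rng.uniform(0, 2 * np.pi, n)
    sc = rng.uniform(0.5, 2.0, n)
    rot = np.stack([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]).transpose(2, 0, 1)
    shift = rng.uniform(-100, 100, (n, 1, 2))
    return np.einsum("nkd,nde->nke", stack, rot) * sc[:, None, None] + shift


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        assert centroid_size(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)) == pytest.approx(
            np.sqrt(2), abs=1e-12
        )

    def test_homogeneous_of_degree_one(self, rng):
        pts = rng.normal(size=(30, 2))
        assert centroid_size(3.7 * pts) == pytest.approx(3.7 * centroid_size(pts), rel=1e-12)

    def test_matches_direct_formula(self, rng):
        pts = rng.normal(size=(30, 2)) * 50
        direct = np.sqrt(np.sum((pts - pts.mean(axis=0)) ** 2))
        assert centroid_size(pts) == pytest.approx(direct, abs=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            centroid_size(np.ones((5, 2)))


class TestAlignPair:
    def test_similarity_transformed_copy_has_zero_distance(self, rng):
        ref = rng.normal(size=(12, 2))
        theta = np.radians(30)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        _, d = align_pair(ref, ref @ rot.T * 2.5 + [10, -4])
        assert d < 1e-10

    def test_identity_alignment(self, rng):
        ref = rng.normal(size=(12, 2))
        aligned, d = align_pair(ref, ref)
        assert d < 1e-12
        unit = (ref - ref.mean(0)) / centroid_size(ref)
        np.testing.assert_allclose(aligned, unit, atol=1e-12)

    def test_matches_exhaustive_rotation_grid(self, rng):
        """Minimised distance agrees with a 0.01-degree rotation grid search."""
        ref = rng.normal(size=(5, 2))
        tgt = rng.normal(size=(5, 2))
        _, d = align_pair(ref, tgt)
        refu = (ref - ref.mean(0)) / centroid_size(ref)
        tgtu = (tgt - tgt.mean(0)) / centroid_size(tgt)
        angles = np.radians(np.arange(0.0, 360.0, 0.01))
        c, s = np.cos(angles), np.sin(angles)
        x = tgtu[:, 0][:, None] * c - tgtu[:, 1][:, None] * s
        y = tgtu[:, 0][:, None] * s + tgtu[:, 1][:, None] * c
        dists = np.sqrt(((x - refu[:, 0][:, None]) ** 2 + (y - refu[:, 1][:, None]) ** 2).sum(0))
        assert d == pytest.approx(dists.min(), abs=1e-4)


class TestGpa:
    def test_one_shape_under_similarity_transforms_collapses(self, rng):
        base = rng.normal(size=(30, 2))
        stack = _random_similarity(np.repeat(base[None], 10, axis=0), rng)
        fit = gpa(stack)
        var = np.sum((fit.aligned - fit.consensus) ** 2)
        assert var < 1e-18

    def test_invariances_and_fixed_point(self, default_fit, rng):
        stack = _random_similarity(default_fit.aligned * 37.0 + 11.0, rng)
        fit2 = gpa(stack)
        assert np.abs(fit2.aligned - default_fit.aligned).max() < 1e-8
        refit = gpa(default_fit.aligned)
        assert np.abs(refit.aligned - default_fit.aligned).max() < 1e-8

    def test_consensus_invariants(self, default_fit):
        assert np.abs(default_fit.consensus.mean(axis=0)).max() < 1e-9
        sizes = np.sqrt((default_fit.aligned**2).sum(axis=(1, 2)))
        assert np.abs(sizes - 1).max() < 1e-9
        assert default_fit.converged


class TestShapeDimension:
    @pytest.mark.parametrize("k,d,expected", [(30, 2, 56), (3, 2, 2), (10, 3, 23)])
    def test_known_values(self, k, d, expected):
        assert shape_dimension(k, d) == expected

    def test_constraint_count_identity(self):
        for k in range(3, 40):
            assert shape_dimension(k, 2) == 2 * k - 2 - 1 - 1


class TestPca:
    def test_percentages_and_trace(self, default_fit):
        res = pca(default_fit)
        assert res.pct_variance.sum() == pytest.approx(100.0, abs=1e-9)
        assert res.eigenvalues.sum() == pytest.approx(res.total_variance, rel=1e-9)

    def test_rank_bound(self, default_fit):
        res = pca(default_fit)
        assert len(res.eigenvalues) <= min(default_fit.n_specimens - 1, 56)
        small = gpa(default_fit.aligned[:10])
        assert len(pca(small).eigenvalues) <= 9

    def test_reconstruction_identity(self, default_fit):
        res = pca(default_fit)
        rec = res.mean + res.scores @ res.vectors
        assert np.abs(rec - res.coordinates).max() < 1e-9

    def test_vectors_orthonormal(self, default_fit):
        res = pca(default_fit)
        gram = res.vectors @ res.vectors.T
        assert np.abs(gram - np.eye(len(gram))).max() < 1e-9


class TestEigenvalueVariance:
    def test_degenerate_spectra(self):
        assert eigenvalue_variance_stats([0.3, 0.3, 0.3], 0.9, 56)[0] == 0.0
        assert eigenvalue_variance_stats([0.5], 0.5, 56)[0] == 0.0

    def test_matches_two_pass_variance(self, rng):
        eig = rng.uniform(0, 1, 20)
        raw, by_total, std = eigenvalue_variance_stats(eig, eig.sum(), 60)
        mean = sum(eig) / len(eig)
        direct = sum((e - mean) ** 2 for e in eig) / len(eig)
        assert raw == pytest.approx(direct, rel=1e-12)
        assert by_total == pytest.approx(direct / eig.sum() ** 2, rel=1e-12)
        assert std == pytest.approx(by_total * 60, rel=1e-12)


class TestProcrustesAnova:
    def test_structural_dfs(self, default_fit, default_dataset):
        la = [c.lunging_aid.value for c in default_dataset]
        time = [int(c.time) for c in default_dataset]
        assert procrustes_anova_shape(default_fit, la).df == 168
        assert procrustes_anova_shape(default_fit, time).df == 56
        assert procrustes_anova_shape(default_fit, la).df_residual == 100 * 56

    def test_ms_is_ss_over_df(self, default_fit, default_dataset):
        row = procrustes_anova_shape(default_fit, [c.lunging_aid.value for c in default_dataset])
        assert row.MS == pytest.approx(row.SS / row.df, rel=1e-12)
        assert 0.0 <= row.p <= 1.0

    def test_permutation_agrees_with_parametric(self):
        spec = PostureEffectSpec(peak=0.6, horse_shape_sd=0.0, horse_size_log_sd=0.0)
        ds = generate_landmark_dataset(effect_spec=spec, seed=42)
        fit = gpa(ds)
        labels = [c.lunging_aid.value for c in ds]
        pp = procrustes_anova_shape(fit, labels, p_method="parametric").p
        pm = procrustes_anova_shape(
            fit, labels, p_method="permutation", n_permutations=10_000, seed=1
        ).p
        assert abs(pp - pm) < 0.02

    def test_single_group_rejected(self, default_fit):
        with pytest.raises(ValueError):
            procrustes_anova_shape(default_fit, ["A"] * default_fit.n_specimens)


class TestCentroidSizeAnova:
    def test_dfs_by_design(self, default_fit, default_dataset):
        la = [c.lunging_aid.value for c in default_dataset]
        time = [int(c.time) for c in default_dataset]
        assert anova_centroid_size(default_fit.centroid_sizes, la).df == 3
        assert anova_centroid_size(default_fit.centroid_sizes, time).df == 1

    def test_two_group_toy_matches_manual_arithmetic(self):
        # groups (1, 2) and (4, 5): SSB = 9, SSW = 1, F = 9 / 0.5 = 18
        row = anova_centroid_size([1.0, 2.0, 4.0, 5.0], ["a", "a", "b", "b"])
        assert row.SS == pytest.approx(9.0, abs=1e-12)
        assert row.SS_residual == pytest.approx(1.0, abs=1e-12)
        assert row.F == pytest.approx(18.0, rel=1e-12)
        assert row.p == pytest.approx(sps.f.sf(18.0, 1, 2), rel=1e-9)


class TestConsensusByClass:
    def test_identical_shapes_return_that_shape(self, rng):
        base = rng.normal(size=(30, 2))
        stack = np.repeat(base[None], 6, axis=0) + rng.normal(0, 1e-3, (6, 30, 2))
        fit = gpa(stack)
        cons = consensus_by_class(fit, ["x"] * 6)
        np.testing.assert_allclose(cons["x"], fit.aligned.mean(axis=0), atol=1e-12)

    def test_balanced_opposite_classes_straddle_grand_mean(self, rng):
        base = rng.normal(size=(30, 2))
        delta = rng.normal(0, 1e-3, (30, 2))
        stack = np.concatenate(
            [np.repeat((base + delta)[None], 5, 0), np.repeat((base - delta)[None], 5, 0)]
        )
        fit = gpa(stack)
        cons = consensus_by_class(fit, ["p"] * 5 + ["m"] * 5)
        midway = (cons["p"] + cons["m"]) / 2
        np.testing.assert_allclose(midway, fit.aligned.mean(axis=0), atol=1e-8)

    def test_mismatched_labels_rejected(self, default_fit):
        with pytest.raises((ValueError, IndexError)):
            consensus_by_class(default_fit, ["a", "b"])

    def test_injected_field_recovered_on_average(self):
        """Averaged over replicates, the before/after consensus difference in
        the rubber-band subset reproduces the injected mid-back elevation."""
        spec = PostureEffectSpec()
        design = StudyDesign(conditions=(LungingAid.RB,))
        fieldvec = spec.displacement_field(LungingAid.RB)
        diffs = np.zeros(30)
        n_rep = 100
        for rep in range(n_rep):
            ds = generate_landmark_dataset(design, spec, seed=900 + rep)
            fit = gpa(ds)
            cons = consensus_by_class(fit, [int(c.time) for c in ds])
            diffs += (cons[1] - cons[0])[:, 1]
        r = np.corrcoef(diffs / n_rep, fieldvec)[0, 1]
        assert r > 0.9


class TestConfidenceEllipse:
    def test_isotropic_gaussian_axes_match_chi_square_quantile(self, rng):
        pts = rng.normal(size=(100_000, 2))
        e = confidence_ellipse(pts, probability=0.9)
        expected = np.sqrt(sps.chi2.ppf(0.9, 2))
        np.testing.assert_allclose(e.semi_axes, expected, rtol=0.03)

    def test_large_sample_coverage(self, rng):
        pts = rng.multivariate_normal([1, -2], [[2.0, 0.7], [0.7, 0.8]], size=100_000)
        e = confidence_ellipse(pts, probability=0.9)
        assert e.contains(pts).mean() == pytest.approx(0.9, abs=0.02)

    def test_rotation_equivariance(self, rng):
        pts = rng.multivariate_normal([0, 0], [[3.0, 0.0], [0.0, 0.5]], size=500)
        theta = 0.6
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        e1 = confidence_ellipse(pts)
        e2 = confidence_ellipse(pts @ rot.T)
        d1 = np.array([np.cos(e1.orientation), np.sin(e1.orientation)])
        d2 = np.array([np.cos(e2.orientation), np.sin(e2.orientation)])
        assert abs(np.abs(d2 @ (rot @ d1))) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(e1.semi_axes, e2.semi_axes, rtol=1e-9)

    def test_singular_covariance_rejected(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="singular"):
            confidence_ellipse(line)
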