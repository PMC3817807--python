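"""Fitting: T/B split, K-means B clustering, alignment, capture rates."""

import numpy as np
import pytest
from scipy import stats

from cytoprofile.fitting import (
    align,
    alignment_delta,
    assign_clusters,
    cluster_b_cells,
    compute_ccr,
    fit_case,
    fit_case_detailed,
    split_t_cells,
)
from cytoprofile.preprocess import Point3Table, preprocess_case
from cytoprofile.profile import Profile
from cytoprofile.synth import cll_spec, generate_case


class TestSplitTCells:
    def test_matches_generator_labels(self, normal_points):
        t_mask = split_t_cells(normal_points)
        pop = normal_points.population
        lymph = np.isin(pop, ["T", "kappa_B", "lambda_B"])
        agree = (t_mask == (pop == "T"))[lymph].mean()
        assert agree >= 0.99

    def test_constant_cd19_rejected(self):
        pts = Point3Table("c", np.tile([1.0, 5.0, 0.0], (30, 1)))
        with pytest.raises(ValueError, match="separation"):
            split_t_cells(pts)

    def test_too_few_events_rejected(self):
        pts = Point3Table("c", np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="at least"):
            split_t_cells(pts)

    def test_labels_partition_events(self, normal_points):
        assignment = assign_clusters(normal_points, k=3, seed=0)
        counts = np.bincount(assignment.labels, minlength=4)[1:]
        assert counts.sum() == len(normal_points)
        assert (counts > 0).all()


class TestClusterBCells:
    def test_single_cluster_center_is_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        labels, centers = cluster_b_cells(X, 1)
        assert (labels == 1).all()
        np.testing.assert_allclose(centers[0], X.mean(axis=0))

    def test_two_clusters_have_opposite_x_signs(self, normal_points):
        t_mask = split_t_cells(normal_points)
        b = normal_points.points[~t_mask]
        _, centers = cluster_b_cells(b, 2, seed=0)
        assert np.prod(centers[:, 0]) < 0

    def test_deterministic_under_permutation(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal([-5, 8, 0], 0.5, size=(150, 3)),
                       rng.normal([5, 8, 0], 0.5, size=(150, 3))])
        _, c1 = cluster_b_cells(X, 2, seed=0)
        _, c2 = cluster_b_cells(X[rng.permutation(len(X))], 2, seed=0)
        order1, order2 = np.argsort(c1[:, 0]), np.argsort(c2[:, 0])
        np.testing.assert_allclose(c1[order1], c2[order2], atol=1e-8)


class TestAlign:
    def test_self_fit_delta_near_zero(self, normal_profile, normal_points):
        assignment = assign_clusters(normal_points, k=3, seed=0)
        delta = alignment_delta(normal_profile, assignment)
        assert np.linalg.norm(delta) < 0.1

    def test_constructed_shift_recovered(self, normal_profile, normal_points):
        v = np.array([2.0, -1.0, 3.0])
        shifted = Point3Table("s", normal_points.points + v, "Normal")
        assignment = assign_clusters(shifted, k=3, seed=0)
        delta = alignment_delta(normal_profile, assignment)
        base = alignment_delta(
            normal_profile, assign_clusters(normal_points, k=3, seed=0))
        np.testing.assert_allclose(delta - base, v, atol=0.05)

    def test_covariances_untouched(self, normal_profile, normal_points):
        assignment = assign_clusters(normal_points, k=3, seed=0)
        aligned = align(normal_profile, assignment)
        np.testing.assert_array_equal(aligned.covariances, normal_profile.covariances)
        assert aligned is not normal_profile


class TestComputeCCR:
    def _toy_profile(self):
        means = np.array([[5.0, 8.0, 0.0], [-5.0, 8.0, 0.0], [0.0, 0.0, 0.0]])
        covs = np.tile(np.eye(3), (3, 1, 1))
        return Profile("Normal", np.full(3, 1 / 3), means, covs, m=2.0, t_index=2)

    def _toy_case(self, b_at):
        rng = np.random.default_rng(0)
        t = rng.normal([0, 0, 0], 0.1, size=(100, 3))
        b = np.tile(np.asarray(b_at, dtype=float), (100, 1))
        return Point3Table("toy", np.vstack([b, t]))

    def test_all_captured_gives_one(self):
        profile = self._toy_profile()
        case = self._toy_case([5.0, 8.0, 0.0])
        assignment = assign_clusters(case, k=3, seed=0)
        assert compute_ccr(align(profile, assignment), case, assignment) == 1.0

    def test_none_captured_gives_zero(self):
        profile = self._toy_profile()
        case = self._toy_case([40.0, 8.0, 40.0])  # far from every B ellipsoid
        assignment = assign_clusters(case, k=3, seed=0)
        assert compute_ccr(align(profile, assignment), case, assignment) == 0.0

    def test_resampled_case_matches_chi2_capture(self, normal_profile):
        rng = np.random.default_rng(21)
        parts = []
        for c in range(normal_profile.k):
            n = int(round(5000 * normal_profile.weights[c]))
            parts.append(rng.multivariate_normal(
                normal_profile.means[c], normal_profile.covariances[c], size=n))
        case = Point3Table("resample", np.vstack(parts), "Normal")
        ccr = fit_case(normal_profile, case, seed=0)
        assert abs(ccr - stats.chi2.cdf(4.0, df=3)) < 0.02

    def test_numerator_matches_bruteforce_mahalanobis(self, normal_profile):
        rng = np.random.default_rng(17)
        pts = rng.normal([0, 5, 0], 4.0, size=(500, 3))
        case = Point3Table("bf", pts)
        assignment = assign_clusters(case, k=3, seed=0)
        aligned = align(normal_profile, assignment)
        ccr = compute_ccr(aligned, case, assignment)

        b_points = pts[~assignment.t_mask]
        count = 0
        for p in b_points:
            inside = False
            for c in aligned.b_indices:
                diff = p - aligned.means[c]
                d2 = diff @ np.linalg.inv(aligned.covariances[c]) @ diff
                inside = inside or np.sqrt(d2) <= aligned.m
            count += inside
        assert ccr == count / len(b_points)


class TestFitCase:
    def test_cohort_discrimination(self, normal_profile, cll_profile, normal_points):
        assert fit_case(normal_profile, normal_points) >= 0.6
        assert fit_case(cll_profile, normal_points) <= 0.3

    def test_mirroring_rescues_opposite_dominance(self, cll_profile):
        lam = preprocess_case(
            generate_case(cll_spec(dominance="lambda", n_events=2000, seed=23)))
        report = fit_case_detailed(cll_profile, lam, seed=0)
        assert report.mirrored
        # unmirrored fit captures essentially nothing
        assignment = assign_clusters(lam, k=2, seed=0)
        unmirrored = compute_ccr(align(cll_profile, assignment), lam, assignment)
        assert report.ccr > unmirrored + 0.5

    def test_translation_invariance_exact(self, normal_profile, normal_points):
        base = fit_case(normal_profile, normal_points, seed=0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            v = rng.integers(-20, 20, size=3).astype(float)
            shifted = Point3Table("s", normal_points.points + v, "Normal")
            assert fit_case(normal_profile, shifted, seed=0) == base

    def test_ccr_monotone_in_m(self, normal_profile, normal_points):
        from dataclasses import replace
        ccrs = [
            fit_case(replace(normal_profile, m=m), normal_points, seed=0)
            for m in (1.0, 2.0, 3.0)
        ]
        assert ccrs[0] <= ccrs[1] <= ccrs[2]

    def test_ccr_bounded(self, normal_profile, cll_profile, normal_points, cll_points):
        for profile in (normal_profile, cll_profile):
            for case in (normal_points, cll_points):
                assert 0.0 <= fit_case(profile, case) <= 1.0
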