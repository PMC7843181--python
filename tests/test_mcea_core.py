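import numpy as np
import pytest
from scipy import stats

from mcea import (
    AnalysisError,
    ClassTooSmallError,
    ConfidenceEllipsoid,
    contains,
    fit_ellipsoid,
    overlap_count,
    self_similarity,
    similarity_matrix,
)
from mcea.pca_reduce import ScoreMatrix


def unit_ellipsoid(center, radius2=stats.chi2.ppf(0.95, 2)):
    return ConfidenceEllipsoid(
        block="b", label="e", center=np.asarray(center, float),
        shape=np.eye(2), level=0.95, radius2=float(radius2),
    )


def make_scores(T, block="b"):
    return ScoreMatrix(block=block, scores=np.asarray(T, float),
                       k=np.asarray(T).shape[1], explained_cum=1.0)


class TestFitEllipsoid:
    def test_large_gaussian_sample_recovers_center_and_radius(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((10_000, 2))
        e = fit_ellipsoid(X, level=0.95)
        np.testing.assert_allclose(e.center, [0, 0], atol=0.05)
        assert e.radius2 == pytest.approx(5.991, abs=0.001)  # chi2(2, 0.95)

    def test_class_too_small(self):
        with pytest.raises(ClassTooSmallError):
            fit_ellipsoid(np.zeros((3, 2)) + np.arange(3)[:, None])

    def test_level_must_be_open_interval(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        for bad in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                fit_ellipsoid(X, level=bad)

    def test_degenerate_covariance_is_regularized(self):
        # collinear points: singular covariance must not crash
        t = np.linspace(0, 1, 20)
        X = np.column_stack([t, 2 * t])
        e = fit_ellipsoid(X)
        assert np.all(np.linalg.eigvalsh(e.shape) > 0)


class TestContains:
    def test_center_inside(self):
        e = unit_ellipsoid([0, 0])
        assert contains(e, np.array([[0.0, 0.0]]))[0]

    def test_distant_point_outside(self):
        e = unit_ellipsoid([0, 0])  # radius2 = 5.991 < 18
        assert not contains(e, np.array([[3.0, 3.0]]))[0]

    def test_boundary_counts_as_inside(self):
        e = unit_ellipsoid([0, 0], radius2=4.0)
        assert contains(e, np.array([[2.0, 0.0]]))[0]

    def test_dimension_mismatch(self):
        e = unit_ellipsoid([0, 0])
        with pytest.raises(ValueError, match="dimension"):
            contains(e, np.zeros((1, 3)))

    def test_vectorized_matches_pointwise_quadratic_form(self):
        """Oracle equivalence: vectorized Mahalanobis membership equals a
        scalar loop over the explicit quadratic form, exactly."""
        rng = np.random.default_rng(5)
        A = rng.standard_normal((2, 2))
        e = ConfidenceEllipsoid(
            block="b", label="e", center=rng.standard_normal(2),
            shape=A @ A.T + 0.5 * np.eye(2), level=0.95,
            radius2=stats.chi2.ppf(0.95, 2),
        )
        pts = rng.standard_normal((200, 2)) * 2
        inv = np.linalg.inv(e.shape)
        loop = np.array([
            (p - e.center) @ inv @ (p - e.center) <= e.radius2 for p in pts
        ])
        np.testing.assert_array_equal(contains(e, pts), loop)


class TestOverlapCount:
    def test_identical_ellipsoids_count_own_members(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 2))
        e = fit_ellipsoid(X)
        own = int(contains(e, X).sum())
        assert overlap_count(e, e, X) == own

    def test_disjoint_ellipsoids_count_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 2))
        e_p = fit_ellipsoid(X)
        e_q = unit_ellipsoid([100.0, 0.0])
        assert overlap_count(e_p, e_q, X) == 0

    def test_hand_laid_two_circle_case(self):
        # unit circles radius2=4 at (0,0) and (1,0); five class-p points
        e_p = unit_ellipsoid([0, 0], radius2=4.0)
        e_q = unit_ellipsoid([1, 0], radius2=4.0)
        pts = np.array([[0, 0], [0.5, 0], [1, 0], [3, 0], [0, 1.9]], float)
        # brute-force per-point oracle
        expected = 0
        for p in pts:
            d_p = ((p - e_p.center) ** 2).sum()
            d_q = ((p - e_q.center) ** 2).sum()
            expected += int(d_p <= 4.0 and d_q <= 4.0)
        assert expected == 3  # (0,0), (0.5,0), (1,0)
        assert overlap_count(e_p, e_q, pts) == expected

    def test_dimension_mismatch(self):
        e2 = unit_ellipsoid([0, 0])
        e3 = ConfidenceEllipsoid("b", "e", np.zeros(3), np.eye(3), 0.95, 7.8)
        with pytest.raises(ValueError):
            overlap_count(e2, e3, np.zeros((1, 2)))


class TestSimilarityMatrix:
    def test_same_distribution_classes_approach_level(self):
        rng = np.random.default_rng(3)
        n = 4000
        T = rng.standard_normal((2 * n, 2))
        labels = ["p"] * n + ["q"] * n
        sim = similarity_matrix(make_scores(T), labels, level=0.95)
        f = sim.to_frame()
        assert f.loc["p", "p"] == pytest.approx(0.95, abs=0.02)
        assert f.loc["p", "q"] == pytest.approx(0.95, abs=0.02)

    def test_duplicated_class_gives_exact_row_equality(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 2))
        T = np.vstack([X, X])
        labels = ["p"] * 50 + ["q"] * 50
        sim = similarity_matrix(make_scores(T), labels)
        f = sim.to_frame()
        assert f.loc["p", "q"] == f.loc["p", "p"]
        assert f.loc["q", "p"] == f.loc["q", "q"]

    def test_distant_classes_share_nothing(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((300, 2))
        b = rng.standard_normal((300, 2)) + np.array([50.0, 0.0])
        sim = similarity_matrix(make_scores(np.vstack([a, b])),
                                ["p"] * 300 + ["q"] * 300, level=0.95)
        f = sim.to_frame()
        assert f.loc["p", "q"] == 0.0
        assert f.loc["p", "p"] == pytest.approx(0.95, abs=0.03)

    def test_values_are_count_ratios(self):
        rng = np.random.default_rng(6)
        T = rng.standard_normal((120, 2))
        labels = (["a"] * 40 + ["b"] * 40 + ["c"] * 40)
        sim = similarity_matrix(make_scores(T), labels)
        assert np.all(sim.values >= 0) and np.all(sim.values <= 1)
        np.testing.assert_array_equal(
            sim.values * sim.class_sizes[:, None], sim.counts
        )

    def test_asymmetry_with_nested_unequal_classes(self):
        """Nested clusters of unequal spread: the tight class sits inside the
        wide class's ellipsoid but not vice versa, so S(p,q) != S(q,p)."""
        rng = np.random.default_rng(7)
        tight = rng.standard_normal((100, 2)) * 0.1
        wide = rng.standard_normal((400, 2)) * 5.0
        sim = similarity_matrix(make_scores(np.vstack([tight, wide])),
                                ["tight"] * 100 + ["wide"] * 400)
        f = sim.to_frame()
        assert f.loc["tight", "wide"] > f.loc["wide", "tight"]

    def test_small_class_dropped_with_record(self, gaussian_classes):
        T, labels = gaussian_classes
        T = np.vstack([T, [[0.0, 0.0]]])
        labels = labels + ["tiny"]
        sim = similarity_matrix(make_scores(T), labels)
        assert sim.dropped == ["tiny"]
        assert "tiny" not in sim.labels

    def test_fewer_than_two_usable_classes_is_error(self):
        T = np.vstack([np.random.default_rng(8).standard_normal((30, 2)),
                       [[0.0, 0.0]]])
        labels = ["p"] * 30 + ["tiny"]
        with pytest.raises(AnalysisError, match="usable classes"):
            similarity_matrix(make_scores(T), labels)

    def test_affine_invariance(self, gaussian_classes):
        """An invertible linear map of all scores leaves every similarity
        value unchanged (Mahalanobis geometry)."""
        T, labels = gaussian_classes
        base = similarity_matrix(make_scores(T), labels).values
        rng = np.random.default_rng(9)
        for _ in range(3):
            A = rng.standard_normal((2, 2))
            while abs(np.linalg.det(A)) < 0.1:
                A = rng.standard_normal((2, 2))
            shifted = T @ A.T + rng.standard_normal(2)
            mapped = similarity_matrix(make_scores(shifted), labels).values
            np.testing.assert_allclose(mapped, base, atol=1e-10)

    def test_monotone_in_confidence_level(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((150, 2))
        b = rng.standard_normal((150, 2)) + np.array([2.0, 0.0])
        T = np.vstack([a, b])
        labels = ["p"] * 150 + ["q"] * 150
        prev = None
        for level in (0.8, 0.9, 0.95, 0.99):
            vals = similarity_matrix(make_scores(T), labels, level=level).values
            if prev is not None:
                assert np.all(vals >= prev - 1e-12)
            prev = vals


def test_self_similarity_routes_through_overlap_count():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((2000, 2))
    s = self_similarity(X, level=0.95)
    e = fit_ellipsoid(X, 0.95)
    assert s == overlap_count(e, e, X) / 2000
    assert s == pytest.approx(0.95, abs=0.02)
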