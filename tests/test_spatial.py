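import numpy as np
import pytest

from kfiber.spatial import (
    SpindleAxes,
    alignment_score,
    classify_inner_outer,
    correlate_length_position,
    fit_spindle_axes,
    interkinetochore_distances,
)


def rot(points, theta):
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return np.asarray(points) @ R.T


class TestAxesFit:
    def test_points_on_diagonal_line(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]])
        axes = fit_spindle_axes(pts)
        assert abs(axes.plate_dir @ np.array([1, 1]) / np.sqrt(2)) == pytest.approx(1.0)

    def test_two_parallel_rows_plate_vertical(self):
        # rows at x = ±3, spread along y: principal direction is vertical
        y = np.linspace(-2, 2, 5)
        pts = np.vstack([np.column_stack([np.full(5, -3.0), y]),
                         np.column_stack([np.full(5, 3.0), y])])
        # make the y-spread dominate so the plate axis is the y direction
        pts[:, 1] *= 3
        axes = fit_spindle_axes(pts)
        assert abs(axes.plate_dir[1]) == pytest.approx(1.0, abs=1e-9)
        assert abs(axes.long_dir[0]) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 2)) * [0.5, 3.0]
        a0 = fit_spindle_axes(pts)
        theta = 0.7
        a1 = fit_spindle_axes(rot(pts, theta))
        assert abs(a1.plate_dir @ rot(a0.plate_dir, theta)) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_spindle_axes(np.array([[0, 0], [1, 1.0]]))


class TestInnerOuter:
    @pytest.mark.parametrize("dist,zone", [
        (1.5, "inner"), (2.0, "inner"), (2.5, "unclassified"),
        (3.0, "outer"), (4.2, "outer"),
    ])
    def test_binning_rule(self, dist, zone):
        assert classify_inner_outer(dist) == zone

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_inner_outer(-0.1)


def _plate_x0() -> SpindleAxes:
    """Axes with the metaphase plate along x = 0 (plate dir = y)."""
    return SpindleAxes(centroid=np.zeros(2), plate_dir=np.array([0.0, 1.0]),
                       long_dir=np.array([1.0, 0.0]))


class TestAlignmentScore:
    def test_under_aligned_positive(self):
        assert alignment_score((1.0, 0), (7.0, 0), _plate_x0()) == pytest.approx(1.0)

    def test_over_aligned_negative(self):
        assert alignment_score((-0.8, 0), (6.5, 0), _plate_x0()) == pytest.approx(-0.8)

    def test_plus_end_on_plate_counts_same_side(self):
        assert alignment_score((0.0, 0), (5.0, 0), _plate_x0()) == pytest.approx(0.0)

    def test_mirror_preserves_magnitude(self):
        axes = _plate_x0()
        s1 = alignment_score((1.2, 0.5), (6.0, 0.2), axes)
        s2 = alignment_score((-1.2, 0.5), (-6.0, 0.2), axes)
        assert abs(s1) == pytest.approx(abs(s2))
        assert s1 == pytest.approx(s2)  # both under-aligned on their own side


class TestCorrelations:
    def test_identical_vectors_r_one(self):
        res = correlate_length_position([1, 2, 3], [1, 2, 3])
        assert res["r"] == pytest.approx(1.0)

    def test_proportional_r_one(self):
        res = correlate_length_position([2, 4, 6], [1, 2, 3])
        assert res["r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_orthogonalized_sample_r_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        y = y - np.polyval(np.polyfit(x, y, 1), x)  # project out x
        res = correlate_length_position(y + 10, x)
        assert res["r"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_length_position([5, 5, 5], [1, 2, 3])

    def test_zone_means_and_test(self):
        lengths = [6, 6.5, 6.2, 9, 9.5, 9.2]
        zones = ["inner"] * 3 + ["outer"] * 3
        res = correlate_length_position(lengths, [1, 1.5, 2, 3, 3.5, 4], zones)
        assert res["outer_mean"] > res["inner_mean"]
        assert res["inner_outer_test"]["p"] < 0.05


class TestInterkinetochore:
    def test_known_distance(self):
        d = interkinetochore_distances({"p0": ((0, 0), (1.2, 0))})
        assert d["p0"] == pytest.approx(1.2)

    def test_coincident_points_zero(self):
        d = interkinetochore_distances({"p0": ((2, 3), (2, 3))})
        assert d["p0"] == 0.0

    def test_unpaired_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="unpaired"):
            d = interkinetochore_distances({"p0": ((0, 0), None)})
        assert d == {}

    def test_fixed_separation_pairs(self):
        rng = np.random.default_rng(2)
        pairs = {}
        for i in range(10):
            a = rng.normal(size=2)
            th = rng.uniform(0, 2 * np.pi)
            pairs[f"p{i}"] = (a, a + [np.cos(th), np.sin(th)])
        d = interkinetochore_distances(pairs)
        assert np.allclose(list(d.values()), 1.0)


class TestRigidInvariance:
    def test_scores_invariant_under_rotation_translation(self):
        rng = np.random.default_rng(3)
        plus = rng.normal(size=(12, 2)) * [0.8, 3.0]
        minus = plus + rng.normal(size=(12, 2)) * [3.0, 0.3] + [6, 0]
        axes = fit_spindle_axes(plus)
        s0 = [alignment_score(p, m, axes) for p, m in zip(plus, minus)]
        d0 = [axes.dist_to_long_axis(p) for p in plus]
        theta, shift = 1.1, np.array([13.0, -4.0])
        plus_r, minus_r = rot(plus, theta) + shift, rot(minus, theta) + shift
        axes_r = fit_spindle_axes(plus_r)
        s1 = [alignment_score(p, m, axes_r) for p, m in zip(plus_r, minus_r)]
        d1 = [axes_r.dist_to_long_axis(p) for p in plus_r]
        np.testing.assert_allclose(np.abs(s0), np.abs(s1), atol=1e-9)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_planted_inner_outer_difference_recovered(self):
        """Outer fibers planted 1.5 µm longer; the Welch comparison should
        find the difference."""
        rng = np.random.default_rng(4)
        n = 30
        inner_d = rng.uniform(0, 2, n)
        outer_d = rng.uniform(3, 5, n)
        zones = ["inner"] * n + ["outer"] * n
        lengths = np.concatenate([rng.normal(7.5, 1.0, n), rng.normal(9.0, 1.0, n)])
        res = correlate_length_position(lengths, np.r_[inner_d, outer_d], zones)
        assert res["inner_outer_test"]["p"] < 0.05
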