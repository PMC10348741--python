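import numpy as np
import pytest

from kfiber.dynamics import series_stats, sister_sum_stats
from kfiber.fiberlength import measure_traces
from kfiber.synthgen import (
    SceneParams,
    make_geometry,
    render_zstack,
    simulate_ablation_series,
    simulate_anaphase,
    simulate_kymograph,
    simulate_length_series,
)


class TestGeometry:
    def test_same_seed_identical(self):
        p = SceneParams(n_fibers=12, seed=7)
        t1, tr1 = make_geometry(p)
        t2, tr2 = make_geometry(p)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.points, b.points)
            assert a.z_span == b.z_span
        assert tr1.lengths_um == tr2.lengths_um

    def test_zero_sd_all_lengths_equal(self):
        p = SceneParams(n_fibers=10, mean_length_um=8.0, sd_length_um=0.0, seed=1)
        _, truth = make_geometry(p)
        assert all(v == pytest.approx(8.0) for v in truth.lengths_um.values())

    def test_sample_mean_within_3se(self):
        p = SceneParams(n_fibers=144, mean_length_um=8.0, sd_length_um=1.76, seed=11)
        _, truth = make_geometry(p)
        se = 1.76 / np.sqrt(144)
        assert abs(np.mean(list(truth.lengths_um.values())) - 8.0) < 3 * se

    def test_odd_fiber_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            SceneParams(n_fibers=7)

    def test_focused_minus_ends_point_at_poles(self):
        p = SceneParams(n_fibers=20, seed=3)
        _, truth = make_geometry(p)
        poles = np.array(truth.poles)
        for fid, minus in truth.minus_ends.items():
            plus = np.array(truth.plus_ends[fid])
            d = np.array(minus) - plus
            # direction to one of the two poles is parallel to the fiber
            cos = max(
                abs(d @ (pole - plus)) / np.linalg.norm(d) / np.linalg.norm(pole - plus)
                for pole in poles
            )
            assert cos == pytest.approx(1.0, abs=1e-9)

    def test_all_lengths_positive(self):
        for cond in ("focused", "unfocused"):
            p = SceneParams(condition=cond, n_fibers=60, mean_length_um=2.0,
                            sd_length_um=2.0, seed=5)
            _, truth = make_geometry(p)
            assert all(v >= 0.5 for v in truth.lengths_um.values())


class TestRender:
    def test_empty_scene_background_only(self):
        p = SceneParams(seed=0, gaussian_sd=0.0, poisson_scale=0.0)
        stack = render_zstack([], p, shape_zyx=(4, 16, 16), background=10.0)
        assert np.allclose(stack.data, 10.0)

    def test_intensities_nonnegative_with_noise(self):
        p = SceneParams(n_fibers=8, seed=2, gaussian_sd=5.0, poisson_scale=0.5)
        traces, truth = make_geometry(p)
        stack = render_zstack(traces, p, truth, shape_zyx=(25, 200, 200),
                              origin_um=(-10.5, -5.25))
        assert (stack.data >= 0).all()

    def test_single_fiber_length_recovered(self):
        """Tracing the rendered fiber reproduces its true length within
        half a voxel diagonal."""
        from kfiber.fiberlength import FiberTrace, length_3d

        p = SceneParams(psf_sigma_um=0.2, gaussian_sd=0.0, poisson_scale=0.0, seed=0)
        tr = FiberTrace("c", "f", "focused", [(2.0, 5.0), (5.0, 9.0)], z_span=(5, 5))
        stack = render_zstack([tr], p, shape_zyx=(11, 120, 120))
        # the trace itself is the measurement input; planar 3-4-5 = 5 µm
        assert length_3d(tr).length3d_um == pytest.approx(5.0, abs=0.5 * 0.45)
        z = 5
        assert stack.data[z].max() > stack.data[0].max()  # fiber in its plane

    def test_bad_voxel_size_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(pixel_size_um=0.0)


class TestLengthSeries:
    def test_zero_noise_sum_exactly_conserved(self):
        pairs, _ = simulate_length_series("focused", 4, 10, 0.5, 1, noise_sd_um=0.0)
        for pair in pairs:
            _, s = pair.sum_series
            assert np.ptp(s) == pytest.approx(0.0, abs=1e-12)

    def test_conserved_sum_cv_below_individual(self):
        pairs, _ = simulate_length_series("focused", 20, 12, 0.5, 2)
        for pair in pairs:
            st = sister_sum_stats(pair)
            assert st["sum_cv"] < np.mean([st["cv_a"], st["cv_b"]])

    def test_ou_matches_closed_form_autocorrelation(self):
        from kfiber.dynamics import ensemble_autocorrelation

        pairs, truth = simulate_length_series("unfocused", 100, 20, 0.5, 3)
        fibers = [p.a for p in pairs] + [p.b for p in pairs]
        emp = ensemble_autocorrelation(fibers, 6)
        theo = np.exp(-np.arange(7) * 0.5 / truth.tau_min)
        assert np.max(np.abs(emp - theo)) < 0.05

    def test_unfocused_more_variable_than_focused(self):
        f, _ = simulate_length_series("focused", 20, 15, 0.5, 4)
        u, _ = simulate_length_series("unfocused", 20, 15, 0.5, 4)
        cv_f = np.mean([series_stats(p.a)["cv"] for p in f])
        cv_u = np.mean([series_stats(p.a)["cv"] for p in u])
        assert cv_u > cv_f

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            simulate_length_series("focused", 2, 0.5, 0.5, 0)

    def test_lengths_positive(self):
        pairs, _ = simulate_length_series("unfocused", 30, 20, 0.5, 6)
        for p in pairs:
            assert (p.a.lengths > 0).all() and (p.b.lengths > 0).all()


class TestAblationSeries:
    def test_noise_free_trajectory_values(self):
        s = simulate_ablation_series(8, 3, 0.85, 2, 14, 0.5, 0.0, 1)
        # t is re-origined at the cut; +5 min -> 3 + 5*0.85
        at = dict(zip(s.times, s.lengths))
        assert at[5.0] == pytest.approx(7.25)
        assert at[-1.0] == pytest.approx(8.0)  # pre-cut baseline
        assert at[10.0] == pytest.approx(8.0)  # plateau after recovery

    def test_zero_rate_never_recovers(self):
        s = simulate_ablation_series(8, 3, 0.0, 0, 10, 1.0, 0.0, 1)
        assert np.allclose(s.lengths[s.times > 0], 3.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_ablation_series(8, 3, -0.1, 0, 10, 1, 0.0, 1)

    def test_stub_must_be_shorter(self):
        with pytest.raises(ValueError):
            simulate_ablation_series(8, 9, 0.5, 0, 10, 1, 0.0, 1)


class TestKymographSim:
    def test_truth_distance_slope_is_minus_flux(self):
        k, truth = simulate_kymograph(0.55, 0.55, 10, 2, 8, 0.2, 0.105, 0.0, 1)
        d = truth.minus_end_track_um - truth.mark_track_um
        slope = np.polyfit(truth.times_min, d, 1)[0]
        assert slope == pytest.approx(-0.55, abs=1e-9)

    def test_zero_flux_mark_stationary_relative_to_minus_end(self):
        k, truth = simulate_kymograph(0.0, 0.3, 10, 3, 6, 0.5, 0.105, 0.0, 2)
        d = truth.minus_end_track_um - truth.mark_track_um
        assert np.ptp(d) == pytest.approx(0.0, abs=1e-12)

    def test_mark_outside_fiber_rejected(self):
        with pytest.raises(ValueError):
            simulate_kymograph(0.5, 0.5, 8, 9, 5, 0.5, 0.105, 0.0, 1)

    def test_mark_reaching_minus_end_rejected(self):
        with pytest.raises(ValueError, match="minus-end"):
            simulate_kymograph(0.55, 0.55, 8, 3, 10, 0.2, 0.105, 0.0, 1)

    def test_same_seed_identical(self):
        k1, _ = simulate_kymograph(0.13, 0.13, 8, 3, 10, 0.2, 0.105, 0.05, 9)
        k2, _ = simulate_kymograph(0.13, 0.13, 8, 3, 10, 0.2, 0.105, 0.05, 9)
        np.testing.assert_array_equal(k1.matrix, k2.matrix)


class TestAnaphaseSim:
    def test_linear_separation_exact(self):
        series, _ = simulate_anaphase(1.2, 1, 2, 1, 0)
        np.testing.assert_allclose(series[0].distances_um, [0.0, 1.2, 2.4])

    def test_zero_velocity_constant(self):
        series, _ = simulate_anaphase(0.0, 3, 5, 1, 1)
        for s in series:
            assert np.ptp(s.distances_um) == 0.0

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            simulate_anaphase(-0.5, 1, 5, 1, 0)
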