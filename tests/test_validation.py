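"""Agreement pipeline: alignment, R²/difference stats, labeling noise,
variance subtraction, benchtop percentile error, segmentation, splines."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import magmicro as mg
from magmicro.exceptions import AlignmentWarning


def series(t, v, flags=None):
    return mg.LengthSeries(np.asarray(t, float), np.asarray(v, float), flags)


@pytest.fixture(scope="module")
def gait_truth():
    cfg = mg.SimConfig(duration=20.0, noise_sd=0.0, dropout=mg.DropoutConfig(rate=0.0), seed=21)
    return mg.gen_gait_trajectory(cfg)


class TestAlignment:
    def test_identical_series_zero_offset(self, gait_truth):
        s = gait_truth.as_length_series()
        assert abs(mg.align_local(s, s, window=0.3)) < 1e-4

    def test_local_recovers_injected_offset(self, gait_truth):
        ref = mg.gen_reference(gait_truth, labeling_noise_sd=0.0, offset=0.037)
        off = mg.align_local(gait_truth.as_length_series(), ref, window=0.5)
        assert off == pytest.approx(0.037, abs=1e-4)

    def test_pure_noise_reference_warns(self, gait_truth):
        rng = np.random.default_rng(0)
        ref = series(gait_truth.t, 35 + rng.standard_normal(len(gait_truth)))
        with pytest.warns(AlignmentWarning):
            mg.align_local(gait_truth.as_length_series(), ref, window=0.2)

    def test_global_recovers_large_offset_with_envelope(self):
        # a speed ramp gives the signal an aperiodic envelope, killing aliases
        cfg = mg.SimConfig(duration=20.0, gait_freq=1.5, gait_freq_end=2.9,
                           noise_sd=0.0, dropout=mg.DropoutConfig(rate=0.0), seed=22)
        truth = mg.gen_gait_trajectory(cfg)
        ref = mg.gen_reference(truth, labeling_noise_sd=0.0, offset=2.3)
        off = mg.align_global(truth.as_length_series(), ref)
        assert off == pytest.approx(2.3, abs=6.45e-3)

    @pytest.mark.parametrize("true_offset", [0.0, 0.1, -0.25])
    def test_global_agrees_with_local_inside_window(self, gait_truth, true_offset):
        ref = mg.gen_reference(gait_truth, labeling_noise_sd=0.0, offset=true_offset)
        mm_series = gait_truth.as_length_series()
        local = mg.align_local(mm_series, ref, window=0.5)
        global_ = mg.align_global(mm_series, ref)
        assert global_ == pytest.approx(local, abs=1e-3)


class TestAgreement:
    def test_perfect_agreement(self, gait_truth):
        s = gait_truth.as_length_series()
        rep = mg.agreement(s, s)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.diff_mean == 0.0 and rep.diff_sd == 0.0

    def test_constant_bias_keeps_r2(self, gait_truth):
        s = gait_truth.as_length_series()
        ref = series(s.t, s.length_mm + 0.5)
        rep = mg.agreement(s, ref)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.diff_mean == pytest.approx(-0.5)
        assert rep.diff_sd == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_rejected(self):
        t = np.arange(10) / 155.0
        with pytest.raises(ValueError):
            mg.agreement(series(t, np.full(10, 35.0)), series(t, np.arange(10.0)))

    def test_labeling_noise_sets_difference_sd(self, gait_truth):
        ref = mg.gen_reference(gait_truth, labeling_noise_sd=0.098, offset=0.0)
        rep = mg.agreement(gait_truth.as_length_series(), ref)
        assert rep.diff_sd == pytest.approx(0.098, abs=0.01)
        assert rep.diff_mean == pytest.approx(0.0, abs=0.01)

    def test_gap_samples_excluded(self, gait_truth):
        s = gait_truth.as_length_series()
        flags = s.flags.copy()
        flags[:100] = "G"
        vals = s.length_mm.copy()
        vals[:100] = np.nan
        gappy = series(s.t, vals, flags)
        rep = mg.agreement(gappy, s)
        assert rep.n_points == len(s) - 100


class TestLabelingNoise:
    def test_identical_labelings_zero(self, gait_truth):
        s = gait_truth.as_length_series()
        est = mg.labeling_noise([s, s, s])
        assert est.sd == 0.0 and est.n_labelings == 3

    def test_two_labelings_constant_gap(self):
        t = np.arange(50) / 155.0
        base = 35 + np.sin(t)
        c = 0.123
        est = mg.labeling_noise([series(t, base - c), series(t, base + c)])
        # two-point sample variance with k−1 is 2c², so sd = c·√2
        assert est.sd == pytest.approx(c * np.sqrt(2))

    def test_recovers_injected_sd(self, gait_truth):
        refs = [
            mg.gen_reference(gait_truth, labeling_noise_sd=0.098, offset=0.0, seed=100 + k)
            for k in range(3)
        ]
        est = mg.labeling_noise(refs)
        assert est.sd == pytest.approx(0.098, abs=0.01)

    def test_requires_two_labelings(self, gait_truth):
        with pytest.raises(ValueError):
            mg.labeling_noise([gait_truth.as_length_series()])


class TestAdjustedSd:
    def test_zero_label_noise_identity(self):
        assert mg.adjusted_sd(0.25, 0.0) == 0.25

    def test_domain_error_when_label_exceeds_diff(self):
        with pytest.raises(ValueError):
            mg.adjusted_sd(0.05, 0.098)

    def test_pythagorean_recovery(self):
        # diff SD built from two independent parts must return the other leg
        a, b = 0.12, 0.07
        assert mg.adjusted_sd(np.hypot(a, b), b) == pytest.approx(a)


class TestE99:
    def test_sort_and_index_oracle(self):
        vals = 40.0 + np.arange(1, 101) * 0.01  # |errors| = 0.01..1.00
        rng = np.random.default_rng(1)
        rng.shuffle(vals)
        got = mg.e99(series(np.arange(100) / 155.0, vals), 40.0)
        errors = np.sort(np.abs(vals - 40.0))
        import math

        oracle = math.ceil(errors[int(np.ceil(0.99 * 100)) - 1] * 1e3 - 1e-9) / 1e3
        assert got == oracle == pytest.approx(0.990)

    def test_all_nominal_zero(self):
        assert mg.e99(series(np.arange(5) / 155.0, np.full(5, 40.0)), 40.0) == 0.0

    def test_single_sample(self):
        assert mg.e99(series([0.0], [40.25]), 40.0) == pytest.approx(0.250)

    def test_rounds_up_to_micrometer(self):
        assert mg.e99(series([0.0], [40.2501234]), 40.0) == pytest.approx(0.251)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mg.e99(np.array([]), 40.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 5.0), min_size=1, max_size=40),
        st.floats(0.0, 10.0),
    )
    def test_monotone_under_large_additions(self, errs, extra):
        base = mg.e99(40.0 + np.array(errs), 40.0)
        if extra >= base:
            grown = mg.e99(40.0 + np.array(errs + [extra]), 40.0)
            assert grown >= base


class TestSegmentGait:
    def test_segments_start_at_toe_strikes(self, gait_truth):
        s = gait_truth.as_length_series()
        strikes = gait_truth.t[gait_truth.toe_strikes]
        segs = mg.segment_gait(s, strikes)
        assert len(segs) == len(strikes) - 1
        starts = np.interp(strikes[:-1], s.t, s.length_mm)
        assert np.allclose([seg[0] for seg in segs], starts, atol=1e-9)

    def test_single_cycle(self, gait_truth):
        s = gait_truth.as_length_series()
        strikes = gait_truth.t[gait_truth.toe_strikes[:2]]
        segs = mg.segment_gait(s, strikes)
        assert len(segs) == 1

    def test_peak_fallback_recovers_period(self):
        cfg = mg.SimConfig(duration=10.0, cycle_jitter=0.0, artifact_amplitude=0.0,
                           noise_sd=0.0, dropout=mg.DropoutConfig(rate=0.0), seed=23)
        truth = mg.gen_gait_trajectory(cfg)
        segs = mg.segment_gait(truth.as_length_series(), toe_strikes=None)
        assert len(segs) >= 8
        # peak-to-peak windows must match the true cycle period
        s = truth.as_length_series()
        dt = np.median(np.diff(s.t))
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(s.length_mm, distance=int(0.25 / dt),
                              prominence=0.25 * np.std(s.length_mm))
        periods = np.diff(s.t[peaks])
        assert np.allclose(periods, 1.0 / cfg.gait_freq, atol=1.0 / 155.0)


def penalized_spline_oracle(x, y, p, grid):
    """Direct dense solve of p·Σ(f(x_i)−y_i)² + (1−p)·∫f″² on a fine grid.

    Represents f by its values on ``grid`` (data points must lie on grid
    nodes); the curvature integral uses second differences.  Independent of
    scipy's spline machinery.
    """
    G = len(grid)
    h = grid[1] - grid[0]
    S = np.zeros((len(x), G))
    idx = np.searchsorted(grid, x)
    for r, i in enumerate(np.clip(idx, 0, G - 1)):
        S[r, i] = 1.0
    D = np.zeros((G - 2, G))
    for i in range(G - 2):
        D[i, i : i + 3] = [1.0, -2.0, 1.0] / h**2
    A = p * S.T @ S + (1 - p) * h * D.T @ D
    return np.linalg.solve(A, p * S.T @ y)


class TestSplineSummary:
    def test_p_equal_one_interpolates(self):
        x = np.linspace(0, 1, 12)
        y = np.sin(2 * np.pi * x) + 0.1 * x
        out = mg.spline_summary(x, y, p=1.0, grid=x)
        assert np.allclose(out.curve, y, atol=1e-9)
        assert np.allclose(out.sd, 0.0, atol=1e-9)

    def test_noiseless_quadratic_reproduced_near_interpolation(self):
        x = np.linspace(0, 1, 25)
        y = 3.0 + 2.0 * (x - 0.4) ** 2
        out = mg.spline_summary(x, y, p=1.0 - 1e-9, grid=x)
        assert np.max(np.abs(out.curve - y)) < 1e-6

    def test_matches_direct_penalized_solve(self):
        grid = np.linspace(0, 1, 401)
        x = grid[::10]  # data on grid nodes
        rng = np.random.default_rng(2)
        y = np.sin(2 * np.pi * x) + 0.05 * rng.standard_normal(len(x))
        p = 0.8
        oracle = penalized_spline_oracle(x, y, p, grid)
        out = mg.spline_summary(x, y, p=p, grid=grid)
        # discretized-curvature oracle agrees to within a small fraction of range
        assert np.max(np.abs(out.curve - oracle)) < 0.02 * np.ptp(y)

    def test_symmetric_noise_about_flat_truth(self):
        rng = np.random.default_rng(3)
        x = np.tile(np.linspace(0, 1, 50), 20)
        y = 35.0 + 0.3 * rng.standard_normal(len(x))
        out = mg.spline_summary(x, y, p=0.8)
        se = 0.3 / np.sqrt(20)
        interior = (out.phase > 0.1) & (out.phase < 0.9)
        assert np.all(np.abs(out.curve[interior] - 35.0) < 3 * se + 0.02)
        assert np.median(out.sd) == pytest.approx(0.3, rel=0.2)

    def test_too_few_distinct_phases_rejected(self):
        with pytest.raises(ValueError):
            mg.spline_summary([0, 0, 1], [1, 2, 3], p=0.8)


class TestAgreementModelSurface:
    def test_fit_local_with_adjustment(self, gait_truth):
        ref = mg.gen_reference(gait_truth, labeling_noise_sd=0.0, offset=0.02)
        fit = mg.LengthAgreement(gait_truth.as_length_series(), ref).fit(
            method="local", label_sd=0.0
        )
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.offset == pytest.approx(0.02, abs=1e-4)
        assert "R^2" in fit.summary()
        assert fit.report.adjusted_sd == pytest.approx(fit.diff_sd)
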