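"""Bead-assay analysis: direction detection, CW bias, reversals, stats."""

import numpy as np
import pytest

from chemosignal import motor
from chemosignal.errors import InsufficientReplicatesError, UndefinedBiasError
from chemosignal.synthetic import (
    JumpPath,
    SwitchingModel,
    simulate_motor_trace,
    trace_from_path,
)
from chemosignal.types import CCW, CW, PAUSE, DirectionSeries, MotorTrace


def circular_trace(speed_hz: float, duration: float, fps: float,
                   radius: float = 0.25, ccw: bool = True,
                   noise_sd: float = 0.0, seed: int = 0) -> MotorTrace:
    """Constant-rotation bead orbit; CCW = increasing angle (math axes)."""
    t = np.arange(int(duration * fps)) / fps
    sign = 1.0 if ccw else -1.0
    theta = sign * 2 * np.pi * speed_hz * t
    rng = np.random.default_rng(seed)
    x = radius * np.cos(theta) + rng.normal(0, noise_sd, len(t))
    y = radius * np.sin(theta) + rng.normal(0, noise_sd, len(t))
    return MotorTrace(t=t, x=x, y=y, fps=fps)


def series_from_states(states, fps: float = 100.0,
                       speed: float = 10.0) -> DirectionSeries:
    states = np.asarray(states, dtype=np.int8)
    t = np.arange(len(states)) / fps
    return DirectionSeries(t=t, state=states,
                           signed_speed_hz=states.astype(float) * speed)


class TestEstimateRotation:
    def test_ccw_rotation_is_negative_speed(self):
        trace = circular_trace(50.0, 2.0, 1000.0, ccw=True)
        rot = motor.estimate_rotation(trace)
        core = slice(100, -100)   # avoid centroid edge effects
        assert np.allclose(rot.signed_speed_hz[core], -50.0, atol=1.0)

    def test_mirrored_trace_flips_chirality(self):
        trace = circular_trace(50.0, 2.0, 1000.0, ccw=True)
        mirrored = MotorTrace(t=trace.t, x=trace.x, y=-trace.y, fps=trace.fps)
        rot = motor.estimate_rotation(mirrored)
        assert np.allclose(rot.signed_speed_hz[100:-100], 50.0, atol=1.0)

    def test_y_axis_down_flag_flips_sign(self):
        trace = circular_trace(20.0, 1.0, 1000.0, ccw=True)
        up = motor.estimate_rotation(trace)
        down = motor.estimate_rotation(trace, y_axis_down=True)
        assert np.allclose(up.signed_speed_hz[100:-100],
                           -down.signed_speed_hz[100:-100], atol=1e-9)

    def test_switch_located_within_5ms(self):
        model = SwitchingModel(rate_ccw_to_cw=1.0, rate_cw_to_ccw=1.0,
                               speed_hz=20.0)
        path = JumpPath(times=np.array([0.0, 30.0]),
                        states=np.array([CCW, CW], dtype=np.int8),
                        t_end=60.0)
        sim = trace_from_path(path, model, fps=1000.0, orbit_radius=0.25,
                              position_noise_sd=0.0,
                              rng=np.random.default_rng(0))
        rot = motor.estimate_rotation(sim.trace)
        ds = motor.classify_direction(rot)
        changes = np.flatnonzero(np.diff(np.sign(ds.state)) != 0)
        t_first = ds.t[changes[0] + 1]
        assert abs(t_first - 30.0) <= 0.005

    def test_degenerate_trace_raises(self):
        t = np.arange(100) / 100.0
        trace = MotorTrace(t=t, x=np.zeros(100), y=np.zeros(100), fps=100.0)
        with pytest.raises(motor.EstimationError):
            motor.estimate_rotation(trace)

    def test_low_snr_warns(self):
        trace = circular_trace(10.0, 1.0, 500.0, radius=0.02, noise_sd=0.02)
        with pytest.warns(UserWarning, match="noise"):
            motor.estimate_rotation(trace)


class TestClassifyDirection:
    def test_constant_positive_speed_is_all_cw(self):
        rot = motor.RotationEstimate(t=np.arange(100) / 100.0,
                                     theta=np.zeros(100),
                                     signed_speed_hz=np.full(100, 10.0),
                                     radius=0.25, fps=100.0)
        ds = motor.classify_direction(rot, pause_threshold=2.0)
        assert np.all(ds.state == CW)

    def test_alternating_blocks_alternate_labels(self):
        fps = 100.0
        speed = np.concatenate([np.full(100, 10.0), np.full(100, -10.0)] * 5)
        rot = motor.RotationEstimate(t=np.arange(len(speed)) / fps,
                                     theta=np.zeros(len(speed)),
                                     signed_speed_hz=speed,
                                     radius=0.25, fps=fps)
        ds = motor.classify_direction(rot, min_dwell=0.05)
        assert not np.any(ds.state == PAUSE)
        assert motor.count_reversals(ds, per_minute=False) == 9

    def test_debounce_removes_glitch_runs(self):
        fps = 1000.0
        speed = np.full(1000, -10.0)
        speed[500:503] = 10.0    # 3 ms glitch, below 10 ms min dwell
        rot = motor.RotationEstimate(t=np.arange(1000) / fps,
                                     theta=np.zeros(1000),
                                     signed_speed_hz=speed,
                                     radius=0.25, fps=fps)
        ds = motor.classify_direction(rot, min_dwell=0.010)
        assert np.all(ds.state == CCW)

    def test_label_agreement_on_noisy_synthetic_trace(self):
        model = SwitchingModel(rate_ccw_to_cw=0.5, rate_cw_to_ccw=0.5,
                               speed_hz=10.0)
        sim = simulate_motor_trace(model, duration=60, fps=500,
                                   position_noise_sd=0.02, seed=4)
        rot = motor.estimate_rotation(sim.trace)
        ds = motor.classify_direction(rot)
        agreement = np.mean(ds.state == sim.truth.state)
        assert agreement >= 0.99


class TestCwBias:
    def test_direct_counts(self):
        ds = series_from_states([CW] * 3 + [CCW] * 7)
        assert motor.compute_cw_bias(ds) == pytest.approx(0.3)

    def test_all_ccw_is_zero(self):
        ds = series_from_states([CCW] * 10)
        assert motor.compute_cw_bias(ds) == 0.0

    def test_pause_frames_excluded(self):
        ds = series_from_states([CW, PAUSE, CCW, PAUSE])
        assert motor.compute_cw_bias(ds) == pytest.approx(0.5)

    def test_all_pause_raises(self):
        ds = series_from_states([PAUSE] * 5)
        with pytest.raises(UndefinedBiasError):
            motor.compute_cw_bias(ds)

    def test_time_reversal_with_mirror_preserves_bias(self):
        model = SwitchingModel(rate_ccw_to_cw=0.4, rate_cw_to_ccw=1.6,
                               speed_hz=10.0)
        sim = simulate_motor_trace(model, duration=60, fps=250,
                                   position_noise_sd=0.0, seed=9)
        tr = sim.trace
        rev = MotorTrace(t=tr.t, x=tr.x[::-1], y=-tr.y[::-1], fps=tr.fps)
        bias_fwd = motor.compute_cw_bias(
            motor.classify_direction(motor.estimate_rotation(tr)))
        bias_rev = motor.compute_cw_bias(
            motor.classify_direction(motor.estimate_rotation(rev)))
        assert bias_rev == pytest.approx(bias_fwd, abs=0.01)


class TestSmoothCwBias:
    def test_constant_direction_gives_constant_series(self):
        ds = series_from_states([CW] * 6000, fps=100.0)
        out = motor.smooth_cw_bias(ds, window=30.0)
        assert np.allclose(out, 1.0)

    def test_step_yields_monotone_transition(self):
        ds = series_from_states([CCW] * 4000 + [CW] * 4000, fps=100.0)
        out = motor.smooth_cw_bias(ds, window=30.0)
        assert np.all(np.diff(out) >= -1e-12)
        assert out[0] == 0.0 and out[-1] == 1.0

    def test_short_recording_falls_back_with_warning(self):
        ds = series_from_states([CW] * 500 + [CCW] * 500, fps=100.0)
        with pytest.warns(UserWarning, match="shorter"):
            out = motor.smooth_cw_bias(ds, window=30.0)
        assert np.allclose(out, 0.5)

    def test_smoothed_mean_matches_whole_window_bias(self):
        """On stationary traces the running-average bias is unbiased."""
        model = SwitchingModel(rate_ccw_to_cw=0.5, rate_cw_to_ccw=1.5,
                               speed_hz=10.0)
        diffs = []
        rng = np.random.default_rng(77)
        for _ in range(60):
            from chemosignal.synthetic import simulate_jump_path
            path = simulate_jump_path(model, 90.0, rng)
            t = np.arange(0, 90.0, 0.01)
            s = path.state_at(t)
            ds = DirectionSeries(t=t, state=s,
                                 signed_speed_hz=s.astype(float) * 10.0)
            diffs.append(np.nanmean(motor.smooth_cw_bias(ds, 30.0))
                         - motor.compute_cw_bias(ds))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-3


class TestCountReversals:
    def test_constant_direction_zero(self):
        ds = series_from_states([CCW] * 12000, fps=100.0)
        assert motor.count_reversals(ds) == 0.0

    def test_strict_alternation_fencepost(self):
        # 60 blocks of 1 s each -> 59 transitions over 60 s
        states = np.repeat([CW, CCW] * 30, 100)
        ds = series_from_states(states, fps=100.0)
        assert motor.count_reversals(ds, per_minute=False) == 59
        assert motor.count_reversals(ds, window=(0.0, 60.0)) == pytest.approx(59.0)

    def test_pause_bridging_convention(self):
        bridged = series_from_states([CCW] * 200 + [PAUSE] * 50 + [CW] * 200)
        returned = series_from_states([CCW] * 200 + [PAUSE] * 50 + [CCW] * 200)
        assert motor.count_reversals(bridged, per_minute=False) == 1
        assert motor.count_reversals(returned, per_minute=False) == 0

    def test_subsampling_invariance_down_to_100fps(self):
        model = SwitchingModel(rate_ccw_to_cw=0.65, rate_cw_to_ccw=0.65,
                               speed_hz=10.0)
        sim = simulate_motor_trace(model, duration=120, fps=1000,
                                   position_noise_sd=0.0, seed=12)

        def count_at(step):
            tr = sim.trace
            sub = MotorTrace(t=tr.t[::step] / 1.0, x=tr.x[::step],
                             y=tr.y[::step], fps=tr.fps / step)
            rot = motor.estimate_rotation(sub)
            return motor.count_reversals(motor.classify_direction(rot),
                                         per_minute=False)

        assert count_at(1) == count_at(5) == count_at(10)


class TestComparePrePost:
    @staticmethod
    def _summaries(values):
        return [motor.MotorSummary(cw_bias=0.5, reversal_rate=v,
                                   mean_speed=10.0, window=(0, 60),
                                   n_frames_cw=10, n_frames_ccw=10,
                                   n_frames_pause=0) for v in values]

    def test_identical_groups(self):
        res = motor.compare_pre_post(self._summaries([2.0, 2.0, 2.0]),
                                     self._summaries([2.0, 2.0, 2.0]))
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_printed_toy_example(self):
        res = motor.compare_pre_post(self._summaries([1.0, 2.0, 3.0]),
                                     self._summaries([4.0, 5.0, 6.0]))
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)
        assert res.pvalue == pytest.approx(0.0214, abs=5e-4)
        assert res.df == 4

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            motor.compare_pre_post(self._summaries([1.0]),
                                   self._summaries([2.0, 3.0]))

    def test_repellent_preset_power(self):
        """Doubled switching rates are detected at p < 0.01 in nearly
        every meta-replicate (power of the pre/post comparison)."""
        from chemosignal.synthetic import simulate_jump_path
        base = SwitchingModel(rate_ccw_to_cw=0.33, rate_cw_to_ccw=1.30,
                              speed_hz=10.0)
        stim = SwitchingModel(rate_ccw_to_cw=0.66, rate_cw_to_ccw=2.60,
                              speed_hz=10.0)
        rng = np.random.default_rng(404)
        hits = 0
        n_meta = 100
        for _ in range(n_meta):
            pre, post = [], []
            for group, model in (("pre", base), ("post", stim)):
                summaries = pre if group == "pre" else post
                for _ in range(20):
                    path = simulate_jump_path(model, 60.0, rng)
                    t = np.arange(0, 60.0, 0.02)
                    s = path.state_at(t)
                    ds = DirectionSeries(
                        t=t, state=s, signed_speed_hz=s.astype(float) * 10.0)
                    summaries.append(motor.summarize_window(ds))
            res = motor.compare_pre_post(pre, post)
            if res.pvalue < 0.01:
                hits += 1
        assert hits >= 95
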