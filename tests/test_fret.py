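"""E-FRET analysis: bleach correction, constants, efficiency, activity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemosignal import fret, presets
from chemosignal.errors import InvalidArgumentError, NormalizationError
from chemosignal.synthetic import (
    BleachModel,
    KinaseStepModel,
    simulate_fret_experiment,
    simulate_single_label_experiment,
)
from chemosignal.types import (
    EfretConstants,
    FretExperiment,
    KinaseActivitySeries,
    SaturatingWindow,
    StimulusSchedule,
)


class TestBleachCorrection:
    def test_noiseless_biexponential_recovered_within_1pct(self):
        t = np.arange(0, 600, 0.05)
        truth = BleachModel(amp1=0.6, tau1=50.0, tau2=500.0)
        y = 1200.0 * truth.decay(t)
        model, corrected = fret.fit_bleach_correction(t, y)
        assert model.amp1 == pytest.approx(0.6, rel=0.01)
        assert model.tau1 == pytest.approx(50.0, rel=0.01)
        assert model.tau2 == pytest.approx(500.0, rel=0.01)
        assert np.allclose(corrected, 1200.0, rtol=1e-6)

    def test_constant_input_is_a_noop(self):
        t = np.arange(0, 100, 0.05)
        y = np.full_like(t, 800.0)
        model, corrected = fret.fit_bleach_correction(t, y)
        assert np.array_equal(corrected, y)
        assert np.allclose(model.decay(t), 1.0)

    def test_corrected_constant_signal_has_flat_trend(self):
        """After correcting a noisy bleached constant signal, an OLS fit
        finds no significant slope (95% CI contains zero)."""
        from scipy import stats
        rng = np.random.default_rng(3)
        t = np.arange(0, 600, 0.05)
        truth = BleachModel(amp1=0.6, tau1=50.0, tau2=500.0)
        y = 1200.0 * truth.decay(t) * (1 + rng.normal(0, 0.01, len(t)))
        _, corrected = fret.fit_bleach_correction(t, y)
        res = stats.linregress(t, corrected)
        ci = 1.96 * res.stderr
        assert abs(res.slope) < ci

    def test_too_few_frames_rejected(self):
        t = np.arange(0, 2, 0.05)
        with pytest.raises(InvalidArgumentError):
            fret.fit_bleach_correction(t, np.ones_like(t))


class TestCalibrateConstants:
    def test_acceptor_only_recovers_a(self, default_constants):
        exps = [simulate_single_label_experiment(
            "acceptor", default_constants, presets.DEFAULT_ACCEPTOR_BLEACH,
            shot_noise_sd=0.01, seed=i) for i in range(3)]
        donor = [simulate_single_label_experiment(
            "donor", default_constants, presets.DEFAULT_DONOR_BLEACH,
            shot_noise_sd=0.01, seed=10 + i) for i in range(3)]
        consts = fret.calibrate_constants(donor, exps, G=2.0)
        assert consts.a == pytest.approx(default_constants.a, rel=0.05)
        assert consts.d == pytest.approx(default_constants.d, rel=0.05)

    def test_zero_crosstalk_model_gives_zero_constants(self):
        zero = EfretConstants(a=0.0, d=0.0, G=2.0)
        acc = [simulate_single_label_experiment("acceptor", zero,
                                                BleachModel.none(), seed=0)]
        don = [simulate_single_label_experiment("donor", zero,
                                                BleachModel.none(), seed=1)]
        consts = fret.calibrate_constants(don, acc, G=2.0)
        assert consts.a == 0.0 and consts.d == 0.0

    def test_g_from_acceptor_bleach_pairs(self):
        acc = [simulate_single_label_experiment(
            "acceptor", EfretConstants(a=0.1, d=0.1, G=2.0),
            BleachModel.none(), seed=0)]
        don = [simulate_single_label_experiment(
            "donor", EfretConstants(a=0.1, d=0.1, G=2.0),
            BleachModel.none(), seed=1)]
        consts = fret.calibrate_constants(don, acc,
                                          acceptor_bleach_pairs=[(150.0, 60.0),
                                                                 (155.0, 62.0)])
        assert consts.G == pytest.approx(2.5, rel=1e-6)
        assert consts.g_provenance == "acceptor-photobleach pairs"


class TestComputeEfret:
    def _exp(self, idd, ida, iaa):
        n = len(idd)
        return FretExperiment(t=np.arange(n, dtype=float), idd=idd, ida=ida,
                              iaa=iaa, bleach_corrected=True)

    def test_half_efficiency_identity(self):
        # a = d = 0 and IDA = G*IDD  ->  E = G*IDD/(G*IDD + G*IDD) = 0.5
        consts = EfretConstants(a=0.0, d=0.0, G=2.0)
        idd = np.full(100, 500.0)
        exp = self._exp(idd, 2.0 * idd, np.full(100, 300.0))
        assert np.allclose(fret.compute_efret(exp, consts), 0.5)

    def test_zero_numerator_identity(self, default_constants):
        idd = np.full(100, 500.0)
        iaa = np.full(100, 300.0)
        ida = default_constants.a * iaa + default_constants.d * idd
        exp = self._exp(idd, ida, iaa)
        assert np.allclose(fret.compute_efret(exp, default_constants), 0.0)

    def test_roundtrip_with_forward_model(self, default_constants,
                                          default_schedule):
        sim = simulate_fret_experiment(
            presets.DEFAULT_KINASE_MODEL, BleachModel.none(),
            BleachModel.none(), default_constants, default_schedule,
            duration=240, shot_noise_sd=0.0, seed=5)
        exp = sim.experiment
        exp.bleach_corrected = True
        e = fret.compute_efret(exp, default_constants)
        assert np.nanmax(np.abs(e - sim.efret_true)) <= 1e-12


@settings(max_examples=30, deadline=None)
@given(scale=st.floats(1e-3, 1e3))
def test_efret_invariant_to_common_channel_rescaling(scale):
    """E_app is a ratio: scaling all channels together changes nothing."""
    consts = EfretConstants(a=0.08, d=0.12, G=2.0)
    rng = np.random.default_rng(42)
    idd = rng.uniform(200, 800, 50)
    iaa = rng.uniform(200, 800, 50)
    ida = rng.uniform(200, 800, 50)
    base = FretExperiment(t=np.arange(50.0), idd=idd, ida=ida, iaa=iaa,
                          bleach_corrected=True)
    scaled = FretExperiment(t=np.arange(50.0), idd=scale * idd,
                            ida=scale * ida, iaa=scale * iaa,
                            bleach_corrected=True)
    e0 = fret.compute_efret(base, consts)
    e1 = fret.compute_efret(scaled, consts)
    assert np.allclose(e0, e1, rtol=1e-9, equal_nan=True)


class TestNormalizeActivity:
    def _schedule(self):
        return StimulusSchedule(saturating_windows=[
            SaturatingWindow(0.0, 10.0, "min"),
            SaturatingWindow(90.0, 100.0, "max")])

    def test_extremes_map_to_zero_and_one(self):
        t = np.arange(0, 100, 0.5)
        e = np.where(t < 50, 0.1, 0.4)
        act = fret.normalize_activity(t, e, self._schedule())
        assert np.allclose(act.activity[t < 10], 0.0)
        assert np.allclose(act.activity[t >= 90], 1.0)

    def test_affine_invariance(self):
        t = np.arange(0, 100, 0.5)
        rng = np.random.default_rng(0)
        e = np.where(t < 50, 0.1, 0.4) + rng.normal(0, 0.005, len(t))
        a0 = fret.normalize_activity(t, e, self._schedule()).activity
        a1 = fret.normalize_activity(t, 3.0 * e + 0.7,
                                     self._schedule()).activity
        assert np.allclose(a0, a1, atol=1e-9)

    def test_mislabeled_windows_raise(self):
        t = np.arange(0, 100, 0.5)
        e = np.where(t < 50, 0.4, 0.1)   # max window sits at the low level
        with pytest.raises(NormalizationError):
            fret.normalize_activity(t, e, self._schedule())

    def test_polarity_flag_inverts(self):
        t = np.arange(0, 100, 0.5)
        e = np.where(t < 50, 0.1, 0.4)
        hi = fret.normalize_activity(t, e, self._schedule()).activity
        lo = fret.normalize_activity(t, e, self._schedule(),
                                     kinase_high_fret=False).activity
        assert np.allclose(hi + lo, 1.0)


class TestAdaptationTime:
    def test_exact_step_return(self):
        t = np.arange(0, 200, 0.1)
        a = np.where((t >= 60) & (t < 120), 0.9, 0.3)
        series = KinaseActivitySeries(t=t, activity=a)
        est = fret.estimate_adaptation_time(series, 60.0, smooth=0.0)
        assert est.responded
        assert est.time == pytest.approx(60.0, abs=0.2)

    def test_flat_trace_flags_no_response(self):
        t = np.arange(0, 120, 0.1)
        series = KinaseActivitySeries(t=t, activity=np.full(len(t), 0.3))
        est = fret.estimate_adaptation_time(series, 60.0)
        assert not est.responded
        assert est.time is None

    def test_exponential_adaptation_in_analytic_band(self, default_constants,
                                                     default_schedule):
        """With adaptation_tau = 20 s the re-entry criterion applied to
        the exponential predicts a crossing between 2*tau and 5*tau."""
        tau = 20.0
        kinase = KinaseStepModel(adaptation_tau=tau)
        sim = simulate_fret_experiment(
            kinase, presets.DEFAULT_DONOR_BLEACH,
            presets.DEFAULT_ACCEPTOR_BLEACH, default_constants,
            default_schedule, duration=240, shot_noise_sd=0.01, seed=8)
        exclude = fret.default_exclude_windows(default_schedule)
        corrected, _, _ = fret.correct_experiment(sim.experiment, exclude)
        e = fret.compute_efret(corrected, default_constants)
        act = fret.normalize_activity(sim.experiment.t, e, default_schedule)
        stim = default_schedule.first_event_time("add")
        est = fret.estimate_adaptation_time(
            act, stim,
            baseline_window=fret.baseline_window_from_schedule(
                default_schedule, stim),
            t_max=fret.adaptation_search_end(default_schedule, stim))
        assert est.responded
        assert 2 * tau <= est.time <= 5 * tau


class TestFullPipeline:
    def test_recovers_ground_truth_activity(self, default_constants,
                                            default_schedule):
        """bleach -> E-FRET -> normalize recovers the simulated
        step-plus-adaptation activity at default noise (10 cells here;
        the 50-cell version lives in the acceptance suite)."""
        errs = []
        for seed in range(10):
            sim = simulate_fret_experiment(
                presets.DEFAULT_KINASE_MODEL, presets.DEFAULT_DONOR_BLEACH,
                presets.DEFAULT_ACCEPTOR_BLEACH, default_constants,
                default_schedule, duration=240, shot_noise_sd=0.01, seed=seed)
            exclude = fret.default_exclude_windows(default_schedule)
            corrected, _, _ = fret.correct_experiment(sim.experiment, exclude)
            e = fret.compute_efret(corrected, default_constants)
            act = fret.normalize_activity(sim.experiment.t, e,
                                          default_schedule)
            errs.append(np.sqrt(np.nanmean(
                (act.activity - sim.activity_true) ** 2)))
        assert np.mean(errs) <= 0.05
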