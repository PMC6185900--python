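"""Nonlinear least-squares decomposition, model-order selection, SNR gate."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from cellwater import (
    DecayCurve,
    DecaySimSpec,
    FitConfig,
    MultiExpModel,
    MultiExponentialFitter,
    compute_snr,
    estimate_component_count,
    evaluate_model,
    fit_multiexponential,
    gate_by_snr,
    generate_decay,
)
from conftest import make_noisy_curve


class TestComponentCountEstimation:
    def test_noiseless_mono_exponential_gives_one(self):
        model = MultiExpModel.from_arrays([100.0], [80.0])
        curve = generate_decay(DecaySimSpec(model=model, snr=math.inf))
        assert estimate_component_count(curve) == 1

    def test_noiseless_well_separated_biexponential_gives_two(self):
        # comparable amplitudes, T2 ratio 5
        model = MultiExpModel.from_arrays([50.0, 50.0], [100.0, 20.0])
        curve = generate_decay(DecaySimSpec(model=model, snr=math.inf))
        assert estimate_component_count(curve) == 2

    def test_constant_signal_gives_one(self):
        curve = DecayCurve(times=np.arange(1.0, 41.0), signal=np.full(40, 7.0))
        assert estimate_component_count(curve) == 1

    def test_short_curve_limits_order_with_warning(self):
        model = MultiExpModel.from_arrays([50.0, 50.0], [100.0, 20.0])
        curve = generate_decay(DecaySimSpec(model=model, n_echoes=7, snr=math.inf))
        with pytest.warns(UserWarning, match="limiting model order"):
            k = estimate_component_count(curve)
        assert k <= 2


class TestNoiselessFitting:
    def test_mono_exponential_exact(self):
        model = MultiExpModel.from_arrays([42.0], [123.0])
        curve = generate_decay(DecaySimSpec(model=model, snr=math.inf))
        fit = fit_multiexponential(curve, 1)
        assert fit.model.amplitudes[0] == pytest.approx(42.0, rel=1e-6)
        assert fit.model.t2s[0] == pytest.approx(123.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_fresh_tissue_parameters_recovered(self, noiseless_curve, fresh_model):
        fit = fit_multiexponential(noiseless_curve, 2)
        np.testing.assert_allclose(fit.model.t2s, fresh_model.t2s, rtol=5e-3)
        np.testing.assert_allclose(fit.model.amplitudes, fresh_model.amplitudes, rtol=5e-3)

    def test_constant_signal_hits_t2_bound_and_flagged(self):
        curve = DecayCurve(times=np.arange(1.0, 41.0), signal=np.full(40, 7.0))
        fit = fit_multiexponential(curve, 1)
        assert fit.model.t2s[0] >= 0.99 * FitConfig().t2_bounds[1]
        assert "t2-at-bound" in fit.flags

    def test_overspecified_order_collapses_and_is_flagged(self):
        model = MultiExpModel.from_arrays([42.0], [123.0])
        curve = generate_decay(DecaySimSpec(model=model, snr=math.inf))
        fit = fit_multiexponential(curve, 2)
        # either one amplitude collapsed to ~0 or the T2s merged; never silent
        assert fit.model.total_amplitude == pytest.approx(42.0, rel=1e-4)
        pred = evaluate_model(fit.model, curve.times)
        np.testing.assert_allclose(pred, curve.signal, rtol=1e-5, atol=1e-8)


class TestFitProperties:
    def test_extra_component_never_worsens_residual(self, fresh_model):
        for seed in range(3):
            curve = make_noisy_curve(fresh_model, snr=20.0, seed=seed)
            r1 = fit_multiexponential(curve, 1).residual_norm
            r2 = fit_multiexponential(curve, 2).residual_norm
            assert r2 <= r1 * (1 + 1e-9)

    def test_rescaling_signal_scales_amplitudes_only(self, fresh_model):
        curve = make_noisy_curve(fresh_model, snr=50.0, seed=7)
        scale = 37.5
        scaled = DecayCurve(times=curve.times, signal=curve.signal * scale, meta=curve.meta)
        fit, fit_s = fit_multiexponential(curve, 2), fit_multiexponential(scaled, 2)
        np.testing.assert_allclose(fit_s.model.t2s, fit.model.t2s, rtol=1e-5)
        np.testing.assert_allclose(
            fit_s.model.amplitudes, fit.model.amplitudes * scale, rtol=1e-5
        )
        assert fit_s.r_squared == pytest.approx(fit.r_squared, abs=1e-9)

    def test_random_two_component_models_recovered_noiselessly(self):
        # T2 ratio >= 2.5, minor fraction >= 5%: recovery to < 0.5% relative
        rng = np.random.default_rng(123)
        for _ in range(50):
            t2_long = rng.uniform(40, 400)
            t2_short = t2_long / rng.uniform(2.5, 10)
            minor = rng.uniform(0.05, 0.5)
            truth = MultiExpModel.from_arrays(
                [100 * (1 - minor), 100 * minor], [t2_long, t2_short]
            )
            curve = generate_decay(DecaySimSpec(model=truth, snr=math.inf))
            fit = fit_multiexponential(curve, 2)
            np.testing.assert_allclose(fit.model.t2s, truth.t2s, rtol=5e-3)
            np.testing.assert_allclose(fit.model.amplitudes, truth.amplitudes, rtol=5e-3)

    def test_noisy_parameter_recovery_spread(self):
        # acquisition-referenced noise at nominal SNR 20; tolerance frozen
        # from the empirical spread of this estimator
        truth = MultiExpModel.from_arrays([70.0, 30.0], [100.0, 20.0])
        rel_errs = []
        for seed in range(30):
            curve = make_noisy_curve(truth, snr=20.0, seed=seed)
            fit = fit_multiexponential(curve, 2)
            rel_errs.append(
                np.max(np.abs(fit.model.t2s - truth.t2s) / truth.t2s)
            )
        assert np.median(rel_errs) < 0.05


class TestSnr:
    def test_adopted_definition(self):
        signal = np.array([41.7, 61.7])  # mean 51.7
        noise = np.array([-1.0, 1.0])
        noise = noise / np.std(noise, ddof=1) * 10.0  # sd exactly 10
        assert compute_snr(signal, noise) == pytest.approx(5.17)

    def test_identical_rois(self, rng):
        roi = rng.normal(10.0, 2.0, size=200)
        assert compute_snr(roi, roi) == pytest.approx(np.mean(roi) / np.std(roi, ddof=1))

    def test_zero_noise_variance_is_infinite(self):
        assert compute_snr([5.0, 5.0], [1.0, 1.0]) == math.inf

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            compute_snr([], [1.0, 2.0])


class TestSnrGate:
    @pytest.mark.parametrize(
        "snr,accepted", [(5.17, True), (5.16, False), (0.0, False), (100.0, True)]
    )
    def test_threshold_with_ties_accepting(self, fresh_model, snr, accepted):
        fit = fit_multiexponential(
            generate_decay(DecaySimSpec(model=fresh_model, snr=math.inf)), 2
        )
        gated = gate_by_snr(fit, snr)
        assert gated.accepted is accepted
        assert gated.snr == snr

    def test_rejected_fit_is_retained_not_deleted(self, fresh_model):
        fit = fit_multiexponential(
            generate_decay(DecaySimSpec(model=fresh_model, snr=math.inf)), 2
        )
        gated = gate_by_snr(fit, 0.1)
        assert gated.model == fit.model
        assert gated.r_squared == fit.r_squared


class TestEstimatorApi:
    def test_fit_predict_roundtrip(self, fresh_model):
        t = 10.0 * np.arange(1, 501)
        y = evaluate_model(fresh_model, t)
        est = MultiExponentialFitter(n_components=2).fit(t.reshape(-1, 1), y)
        np.testing.assert_allclose(est.predict(t.reshape(-1, 1)), y, rtol=1e-6)
        assert est.n_components_ == 2
        assert est.score(t.reshape(-1, 1), y) == pytest.approx(1.0, abs=1e-9)

    def test_clone_and_params(self):
        est = MultiExponentialFitter(n_components=1, n_starts=4)
        cloned = clone(est)
        assert cloned.get_params()["n_components"] == 1
        cloned.set_params(n_components=2)
        assert cloned.n_components == 2

    def test_unsorted_input_accepted(self, fresh_model):
        t = 10.0 * np.arange(1, 201)
        y = evaluate_model(fresh_model, t)
        perm = np.random.default_rng(0).permutation(len(t))
        est = MultiExponentialFitter(n_components=2).fit(t[perm], y[perm])
        np.testing.assert_allclose(est.model_.t2s, fresh_model.t2s, rtol=1e-3)

    def test_auto_order_on_noiseless_biexponential(self):
        model = MultiExpModel.from_arrays([50.0, 50.0], [100.0, 20.0])
        curve = generate_decay(DecaySimSpec(model=model, snr=math.inf))
        est = MultiExponentialFitter(n_components="auto").fit(curve.times, curve.signal)
        assert est.n_components_ == 2
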