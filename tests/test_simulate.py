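"""Seed-determinism and ground-truth fidelity of the generators."""

import math

import numpy as np
import pytest

from cellwater import (
    DecaySimSpec,
    DryingSimSpec,
    PhantomSpec,
    compare_series,
    compute_snr,
    detect_rupture_events,
    entropy_threshold,
    evaluate_model,
    generate_decay,
    generate_drying_series,
    generate_noise_roi,
    generate_phantom,
    generate_signal_roi,
    segment,
)


class TestGenerateDecay:
    def test_infinite_snr_is_exact_model(self, fresh_model):
        curve = generate_decay(DecaySimSpec(model=fresh_model, snr=math.inf))
        np.testing.assert_array_equal(
            curve.signal, evaluate_model(fresh_model, curve.times)
        )
        assert len(curve) == 1000
        assert curve.times[0] == 10.0 and curve.times[-1] == 10000.0

    @pytest.mark.parametrize("noise_model", ["gaussian", "rician"])
    def test_seed_determinism(self, fresh_model, noise_model):
        spec = DecaySimSpec(model=fresh_model, snr=8.0, noise_model=noise_model, seed=11)
        a, b = generate_decay(spec), generate_decay(spec)
        np.testing.assert_array_equal(a.signal, b.signal)
        other = generate_decay(
            DecaySimSpec(model=fresh_model, snr=8.0, noise_model=noise_model, seed=12)
        )
        assert not np.array_equal(a.signal, other.signal)

    def test_rician_magnitudes_nonnegative(self, fresh_model):
        spec = DecaySimSpec(
            model=fresh_model, snr=3.0, noise_model="rician", roi_voxels=1, seed=5
        )
        assert np.all(generate_decay(spec).signal >= 0)

    def test_gaussian_snr_round_trip(self, fresh_model):
        # measured image SNR (sample ROI mean over noise ROI sd) ~ nominal
        measured = []
        for seed in range(20):
            spec = DecaySimSpec(
                model=fresh_model, snr=5.17, noise_model="gaussian", seed=seed
            )
            measured.append(
                compute_snr(generate_signal_roi(spec, 400), generate_noise_roi(spec, 400))
            )
        assert np.mean(measured) == pytest.approx(5.17, rel=0.05)

    def test_roi_averaging_reduces_curve_noise(self, fresh_model):
        lone = generate_decay(
            DecaySimSpec(model=fresh_model, snr=10.0, noise_model="gaussian",
                         roi_voxels=1, seed=3)
        )
        pooled = generate_decay(
            DecaySimSpec(model=fresh_model, snr=10.0, noise_model="gaussian",
                         roi_voxels=900, seed=3)
        )
        clean = evaluate_model(fresh_model, lone.times)
        assert np.std(pooled.signal - clean) < np.std(lone.signal - clean) / 10


class TestGenerateDryingSeries:
    def test_quiet_protocol_is_constant(self):
        spec = DryingSimSpec(temperature_c=45.0, rupture_times=(), fluctuation_sd=0.0)
        series, _ = generate_drying_series(spec)
        np.testing.assert_allclose(series.icw_pct, spec.baseline_icw_pct)

    def test_single_planted_rupture_is_detectable_once(self):
        spec = DryingSimSpec(rupture_times=(120.0,), drop_pp=30.0, fluctuation_sd=0.0)
        series, _ = generate_drying_series(spec)
        events = detect_rupture_events(series, 15.0)
        assert [e.time for e in events] == [120.0]
        assert events[0].drop_pp == pytest.approx(30.0)

    def test_partial_rebound_after_rupture(self):
        spec = DryingSimSpec(
            rupture_times=(90.0,), drop_pp=30.0, recovery_rate=0.5, fluctuation_sd=0.0
        )
        series, _ = generate_drying_series(spec)
        i = list(series.times).index(90.0)
        post = series.icw_pct[i]
        assert series.icw_pct[i + 1] == pytest.approx(
            post + 0.5 * (spec.baseline_icw_pct - post)
        )

    def test_temperature_protocols_order_first_events(self):
        hot = DryingSimSpec(
            temperature_c=70.0, rupture_times=(60.0, 150.0), seed=1, fluctuation_sd=1.0
        )
        warm = DryingSimSpec(
            temperature_c=60.0, rupture_times=(90.0, 180.0), seed=2, fluctuation_sd=1.0
        )
        df = compare_series(
            [generate_drying_series(s)[0] for s in (warm, hot)], min_drop_pp=15.0
        ).set_index("temperature_c")
        assert df.loc[70.0, "first_event_min"] < df.loc[60.0, "first_event_min"]

    def test_decay_specs_carry_truth_fractions(self):
        spec = DryingSimSpec(rupture_times=(90.0,), drop_pp=25.0, seed=4)
        series, dspecs = generate_drying_series(spec)
        assert len(dspecs) == len(series)
        for icw, ds in zip(series.icw_pct, dspecs):
            amps = ds.model.amplitudes
            assert 100 * amps[0] / amps.sum() == pytest.approx(icw)
            assert list(ds.model.t2s) == [spec.t2_long_ms, spec.t2_short_ms]

    def test_seed_determinism(self):
        spec = DryingSimSpec(rupture_times=(90.0,), seed=9)
        a, _ = generate_drying_series(spec)
        b, _ = generate_drying_series(spec)
        np.testing.assert_array_equal(a.icw_pct, b.icw_pct)

    def test_oversized_drop_rejected(self):
        spec = DryingSimSpec(baseline_icw_pct=40.0, rupture_times=(90.0,), drop_pp=45.0)
        with pytest.raises(ValueError, match="exceeds current"):
            generate_drying_series(spec)

    def test_rupture_times_must_be_sampled(self):
        with pytest.raises(ValueError):
            DryingSimSpec(rupture_times=(95.0,))


class TestGeneratePhantom:
    def test_intact_lattice_truth_matches_segmentation(self):
        spec = PhantomSpec(broken_fraction=0.0, wall_sd=0.0, lumen_sd=0.0, seed=0)
        image, truth = generate_phantom(spec)
        result = segment(image, entropy_threshold(image))
        np.testing.assert_array_equal(result.mask, truth)
        assert result.wall_fraction == pytest.approx(truth.mean())

    def test_noiseless_broken_lattice_recovered_pixel_perfect(self):
        # air filled at lumen intensity: two grey classes, exact separation
        spec = PhantomSpec(
            broken_fraction=0.3, wall_sd=0.0, lumen_sd=0.0, air_sd=0.0,
            air_mean=60.0, seed=2,
        )
        image, truth = generate_phantom(spec)
        result = segment(image, entropy_threshold(image))
        np.testing.assert_array_equal(result.mask, truth)

    def test_noisy_phantom_wall_fraction_close_to_truth(self):
        image, truth = generate_phantom(PhantomSpec(seed=1))
        result = segment(image, entropy_threshold(image))
        assert result.wall_fraction == pytest.approx(truth.mean(), abs=0.05)

    def test_seed_determinism(self):
        a, _ = generate_phantom(PhantomSpec(seed=7))
        b, _ = generate_phantom(PhantomSpec(seed=7))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_thin_cells_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(cell_diameter_px=5, wall_thickness_px=3)


def test_decay_spec_validation():
    from cellwater import MultiExpModel

    model = MultiExpModel.from_arrays([1.0], [50.0])
    with pytest.raises(ValueError):
        DecaySimSpec(model=model, n_echoes=3)
    with pytest.raises(ValueError):
        DecaySimSpec(model=model, snr=-1.0)
    with pytest.raises(ValueError):
        DecaySimSpec(model=model, noise_model="poisson")
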