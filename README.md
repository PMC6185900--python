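# cellwater

Cellular-water transport analysis for plant tissue during drying: NMR
T₂-relaxometry decay decomposition, water-compartment tracking,
membrane-rupture detection, and micro-CT image segmentation.

## The problem

Plant (bio-food) tissue holds most of its water inside cells.  During
hot-air drying, water leaves either *symplastically* — cell to cell through
micro-capillaries, with membranes intact — or *apoplastically*, when
membranes rupture and intracellular water (ICW) spills into the
intercellular space as free water (FW).  Which pathway dominates, and when
ruptures happen, can be read out non-invasively from ¹H-NMR T₂ relaxometry:
water in different compartments relaxes with different spin–spin time
constants, so a CPMG/MSME echo train decays multi-exponentially,

$$Z(t) = \sum_i M_i \, e^{-t/T_2^i},$$

with the long-T₂ component (≈ 90–150 ms) carrying the ICW share and the
short-T₂ component (≈ 15–70 ms) the FW share.  Tracking the ICW percentage
over drying time gives a sawtooth: abrupt drops mark rupture events,
partial rebounds mark evaporation of the freed water.  Micro-CT slices of
the dried tissue provide the morphological cross-check: the solid cell-wall
matrix images bright and can be isolated by maximum-entropy (Kapur)
histogram thresholding.

This package implements that full analysis for researchers in food-process
engineering and tissue biophysics, together with seeded synthetic
generators (decay curves, drying protocols with planted ruptures, and
cell-lattice phantoms) so every stage can be validated against known ground
truth.

## What is inside

| Stage | Estimator / functions |
| --- | --- |
| Decay decomposition | `MultiExponentialFitter`, `fit_multiexponential`, `estimate_component_count` — variable-projection NLLS with deterministic multi-start; BIC-scored piecewise-linear ln-signal segmentation for model order |
| Quality gate | `compute_snr`, `gate_by_snr` — mean(sample ROI)/sd(noise ROI), acceptance at SNR ≥ 5.17 |
| Compartments | `assign_compartments`, `build_series`, `detect_rupture_events` / `RuptureDetector`, `compare_series` |
| Segmentation | `MaxEntropyThresholder`, `entropy_threshold`, `segment`, `wall_fraction_profile` |
| Synthetic data | `generate_decay`, `generate_drying_series`, `generate_phantom` (+ spec dataclasses) |
| Reference data | `cellwater.datasets` — bundled bi-exponential decompositions of apple tissue dried at 45/60/70 °C |
| Orchestration | `cellwater.io.run_pipeline`, `RunConfig`, and the `cellwater` CLI (`fit`, `analyze-series`, `segment`, `simulate`, `run`) |

The fitter, thresholder and rupture detector follow scikit-learn estimator
conventions (`fit`, `predict`/`transform`, `get_params`, fitted attributes
with trailing underscores) and compose with sklearn tooling.

## Worked example

Decompose a simulated echo train (1000 echoes, 10 ms spacing) acquired at
the per-voxel image SNR acceptance gate of 5.17, from tissue whose true
decomposition is 88.10% ICW at T₂ 90.67 ms and 11.97% FW at 32.76 ms:

```python
from cellwater import (DecaySimSpec, MultiExpModel, assign_compartments,
                       fit_multiexponential, generate_decay)

truth = MultiExpModel.from_arrays([88.10, 11.97], [90.67, 32.76])
curve = generate_decay(DecaySimSpec(model=truth, snr=5.17,
                                    noise_model="gaussian", seed=1))
fit = fit_multiexponential(curve, 2)
icw, fw = assign_compartments(fit)
print(f"T2 long/short: {fit.model.t2s[0]:.1f} / {fit.model.t2s[1]:.1f} ms")
print(f"ICW {icw:.1f}% / FW {fw:.1f}%  (R^2 = {fit.r_squared:.4f})")
```

```
T2 long/short: 89.1 / 26.6 ms
ICW 90.5% / FW 9.5%  (R^2 = 0.9932)
```

The fitted T₂ pair and ICW share land within the few-percentage-point
scatter expected at this noise level, and the R² matches the ≈ 0.99 values
typical of gated acquisitions.  Scanning the bundled 60 °C drying series
with the default 15-percentage-point drop rule finds the four rupture
events:

```python
from cellwater import detect_rupture_events
from cellwater.datasets import icw_series

for e in detect_rupture_events(icw_series(60), min_drop_pp=15):
    print(f"rupture at {e.time:.0f} min (drop {e.drop_pp:.1f} pp)")
```

```
rupture at 90 min (drop 33.2 pp)
rupture at 180 min (drop 25.0 pp)
rupture at 270 min (drop 22.7 pp)
rupture at 360 min (drop 56.9 pp)
```

Each event is stamped at the first 30-min measurement where the drop is
observable.  The 45 °C series yields no events (symplastic regime), and the
70 °C series ruptures earlier than the 60 °C one — the temperature ordering
the method is designed to resolve.

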