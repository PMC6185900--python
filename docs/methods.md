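# Methods

## Signal model and assumptions

A CPMG/MSME echo train from tissue with several water compartments is
modelled as a discrete sum of 1–3 exponentials,

    Z(t) = Σᵢ Mᵢ · exp(−t / T₂ⁱ),

under the usual slow-exchange assumption: water does not move between
compartments on the NMR timescale, so each compartment keeps its own T₂.
Amplitudes `Mᵢ` are the t = 0 extrapolations of each component and are kept
in arbitrary units; compartment percentages are a normalised view computed
downstream (`assign_compartments`), never stored in the model.  Components
are canonically ordered by descending T₂ so that index 0 is always the
"long" (intracellular-water) component.  Times are milliseconds throughout;
the default acquisition grid is 1000 echoes at 10 ms spacing.

The package deliberately fits *discrete* components rather than a
continuous T₂ spectrum (no NNLS/inverse-Laplace spectrum): for two
well-separated tissue compartments the discrete model is the standard and
far better-conditioned choice.

## Fitting: variable projection with multi-start

`MultiExponentialFitter` minimises the sum of squared residuals over the
T₂ values only (log-parameterised, trust-region-reflective solver); for
each candidate T₂ set the amplitudes are solved exactly by non-negative
linear least squares.  This halves the search dimension, enforces Mᵢ ≥ 0,
and removes most sensitivity to initial values.  Initialisation is a
deterministic multi-start: k-subsets of a log-spaced T₂ grid spanning the
sampled time window (8 starts by default); the best final residual wins, so
repeated fits are bit-reproducible without any random seed.

Numerical choices:

* **T₂ bounds.** Configured as [0.1, 10000] ms, but the optimiser's
  effective lower bound is raised to half the first echo time.  A component
  decaying faster than the sampling grid influences only the first echo;
  its t = 0 amplitude is then essentially unconstrained (fitted amplitudes
  of ~10¹¹ were observed at T₂ ≈ 0.4 ms with 10 ms echoes) and it destroys
  amplitude-fraction estimates.  Such components are not resolvable by the
  acquisition, so they are excluded by construction rather than reported.
* **Degeneracies.** If two fitted T₂ values coincide within 10⁻⁶ relative,
  the components are merged (amplitudes summed) and the fit is flagged
  `components-merged`; a zero amplitude in a multi-component fit flags
  `component-collapsed`; a T₂ within 1% of a bound flags `t2-at-bound`
  (the constant-signal degenerate input lands here with T₂ at the upper
  bound).  Flagged fits are returned, never silently repaired.
* **R²** is 1 − SSres/SStot, clipped to [0, 1]; a constant signal
  (SStot = 0) gets R² = 1 only for an exact fit.

## Model-order selection

The ln-signal of a k-exponential decay consists of k near-linear regimes.
`estimate_component_count` segments (t, ln Z) into k contiguous straight
lines by exact dynamic programming (optimal piecewise-linear SSE, minimum
segment length 3, curves subsampled to ≤ 200 points) and scores each order
with

    score(k) = m·ln((SSE_k + m·s₀²)/m) + (3k − 1)·ln(m),

choosing the minimum (ties prefer fewer components).  The resolution floor
`s₀ = 0.01 × (ln-signal range)` is essential: on noiseless data the
residual of a piecewise-linear fit is approximation error, not noise, so an
unfloored BIC always rewards more segments.  With the floor, structure
smaller than ~1% of the dynamic range is not counted as evidence for
another component; a mono-exponential selects k = 1 and a well-separated
bi-exponential (T₂ ratio ≥ 5, comparable amplitudes) selects k = 2.  Only
samples with signal above 1% of the initial signal enter, which confines
the analysis to the informative early window rather than the noise-floor
tail.  This score is the package's concrete, deterministic formalisation of
the visual "count the linear regimes in the log-plot" practice.

## SNR definition, gate, and noise emulation

SNR is mean(sample ROI) / sd(noise ROI) — the common magnitude-MR
convention; the noise ROI sits outside the sample.  Fits from acquisitions
below the gate (default 5.17, the empirical threshold at which
four-parameter bi-exponential fits stay stable) are flagged
`accepted=False` and excluded from series assembly; they are never deleted
and never interpolated over, since interpolation could fabricate or hide
rupture drops.

The synthetic generator mirrors how such data are actually acquired.  The
quoted SNR is a *per-voxel image* quantity, but the decay that gets fitted
is the mean over a region of interest covering the sample, so its noise is
the per-voxel noise divided by √(ROI size).  `DecaySimSpec.roi_voxels`
(default 1162 — a disc of 18 mm sample diameter at 468 µm in-plane
resolution) sets that divisor; `roi_voxels=1` gives raw single-voxel
curves.  The default reproduces the observable signature of real gated
data: at nominal SNR 5.17 the bi-exponential fits return R² ≈ 0.993 and
ICW-share scatter of a few percentage points, matching the R² ≈ 0.98–0.9999
and replicate scatter of published drying decompositions.  Without the ROI
emulation (per-voxel noise applied directly to the curve), the same nominal
SNR gives R² ≈ 0.1 and the two components are information-theoretically
inseparable — even an estimator that knows the true T₂ pair and solves only
the amplitudes has a median ICW-share error of ≈ 12 pp.

Magnitude data are Rician; the generator's default noise model takes the
magnitude of a complex Gaussian signal, and a plain Gaussian option exists
for analytic tests (Gaussian noise-floor samples may go negative; they are
retained for fitting, which operates on the linear scale, and dropped only
from log-space views).  At the gate SNR and above, fitting ignores the
Rician bias (Gaussian approximation), the standard practice at SNR ≳ 3.
Note that a mean/sd SNR measured from Rayleigh-distributed noise-ROI
magnitudes sits above the nominal per-channel value (sd ≈ 0.655 σ); the
Gaussian option round-trips exactly.

## Compartments and rupture detection

For an accepted two-component fit, ICW% = 100·M_long/(M_long + M_short) and
FW% = 100 − ICW%, so the pair sums to 100 exactly at every point.  One- or
three-component fits raise an error: a mono-exponential decay does not
resolve compartments, and no assignment is defined here for a third
(cell-wall bound water) component, which is a few percent of total water
and is not fitted in this analysis.

`RuptureDetector` scans the ICW series for one-step drops that are strictly
positive and ≥ `min_drop_pp` (default 15 pp).  The default separates
genuine membrane-collapse drops in hot-air drying data (≥ ~22 pp at
60–70 °C) from the ≤ ~6 pp fluctuations of low-temperature protocols.
Events are stamped at the post-drop measurement — with 30-min sampling,
the first time the drop is observable.  `min_drop_pp = 0` marks every
strictly decreasing step; `min_drop_pp = ∞` marks none.

## Segmentation

The Kapur maximum-entropy threshold maximises the sum of Shannon entropies
of the two histogram classes over all 255 candidate cuts; empty bins
contribute zero entropy (0·log 0 := 0) and ties break to the lowest
maximising cut, making the result deterministic.  Imaging physics fixes the
mask convention: the solid cell-wall matrix reflects X-rays and images
bright, so mask value 1 = intensity ≥ threshold = solid, and the wall
(solid) fraction is the mask mean.  Stacks are handled slice-wise with a
per-slice threshold.  `wall_fraction_profile` resolves the solid fraction
along one axis (row 0 = sample surface by convention), which quantifies a
rupture front advancing from the surface.

## Synthetic generators

All generators are seed-deterministic (NumPy `default_rng`).

* **Decay curves** — exact model values at infinite SNR; otherwise noise
  referenced to the first-echo signal as described above.
* **Drying series** — ICW% starts at a baseline (default 88%), drops by a
  planted amount at each rupture time, relaxes back toward baseline at
  `recovery_rate` per 30-min step between ruptures (the freed water
  evaporates, raising the *relative* ICW share), and jitters with small
  Gaussian fluctuations elsewhere.  Each time point also yields the decay
  spec whose amplitude fractions equal the trajectory truth (default truth
  T₂ pair 95/30 ms, matching the magnitudes of real long/short components),
  so the full fit → fractions → events chain closes end to end.  A drop
  that would push ICW below zero raises an error.
* **Phantoms** — a square cell lattice (default 256² px, 32 px cells, 3 px
  walls) with bright walls over dark lumen and the wall mask recorded as
  truth.  `broken_fraction` erases wall segments with probability
  decreasing linearly from the top edge ("surface"), emulating a rupture
  front; erased pixels take an air intensity.

What the generators do *not* emulate: T₂ drift with moisture content
(each synthetic time point reuses one truth T₂ pair, whereas real long-T₂
values wander over drying), diffusion and exchange effects on the echo
train, B₁/B₀ inhomogeneity, structured (non-white) image noise, irregular
cell geometry, and scanner artefacts.  Passing tests therefore demonstrate
correctness of the estimators under the stated statistical model, not
robustness to every property of real acquisitions.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use 1000-echo decays for
round-trip and noise studies (100 seeds at the gate SNR), 16-echo curves
against a dense 40×40 grid-search oracle (50 random models), 14-point
drying grids over 20 seeds for end-to-end closure, and 256² px phantoms.
These sizes make the whole suite run in a couple of minutes on one CPU
while leaving every statistical margin wide.

## Known limitations

* Per-curve bi-exponential fitting is intrinsically ill-conditioned at low
  curve-level SNR when T₂ ratios are ≲ 3; below an effective curve SNR of
  ~100 the T₂–amplitude trade-off widens quickly (the reported flags and
  the SNR gate exist precisely to keep such fits out of series).
* Compartment assignment is defined for two components only; tri-exponential
  tissue models require an assignment convention this analysis does not
  prescribe.
* The rupture scan is a one-step differencing rule on a discrete grid; it
  cannot place an event between measurements, and a rupture smaller than
  the threshold or slower than one sampling interval is reported as
  fluctuation, not collapse.
* Segmentation is plain global thresholding: no instance separation,
  watershed, or pore-network extraction, and per-slice thresholds can
  differ across a stack with intensity drift.
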