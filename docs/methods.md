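# Methods

## Exchange model

Each of the `n_myosins` (default 300) sites of a bipolar thick filament
(default 1.6 µm, inside a 2.0 µm sarcomere so the tips sit at ±0.8 in
normalized coordinates) is treated as an independent exchange unit:
site *i* swaps its occupant for a molecule from the cytosolic pool as a
Poisson process with rate kᵢ (h⁻¹). Because sites do not interact,
drawing per-site exponential waiting times is exactly equivalent to a
Gillespie simulation, occupancy is conserved (one molecule out, one in
per event), and the replaced fraction is non-decreasing. No
cooperativity, no MybpC/myomesin/titin mechanics, no contraction: zone
structure enters only through the shape of the rate profile.

Two rate descriptions are interchangeable:

* **Pool model** `(A_i, k_i)`: fractions of sites exchanging at discrete
  rates, `f(t) = Σ A_i (1 − e^{−k_i t})`, with `1 − Σ A_i` immobile —
  this is what keeps fitted mobile fractions below 100%. When a pool
  model is placed on a filament, faster pools occupy more peripheral
  sites (exchange is fastest at the tips); the ensemble curve is
  unaffected by that placement.
* **Spatial profile** `k(|x|) = k_c + (k_t − k_c)(|x|/x_tip)^p`:
  `tip_biased()` enforces `k_t ≥ k_c` (monotone non-decreasing in |x|);
  `profile()` allows the decreasing case (center-weighted exchange).

`calibrate_biphasic` solves a two-pool model through a table of
(time, replaced-fraction) anchors by bounded least squares with
multi-start over k₂, demanding every anchor be reproduced to 1e-6 (a
`CalibrationError` with residuals otherwise). The shipped
`biphasic_red` preset uses the anchors (10 min, 0.20), (60 min, 0.30),
(600 min, 0.70) with the fast rate fixed at 30 h⁻¹, giving
A₁ = 0.1790, A₂ = 0.5752, k₂ = 0.2362 h⁻¹ and an immobile fraction of
0.246. The `monoexp_green` / `monoexp_red` presets are single pools
with mobile fractions 55.24% / 66.98% and half-lives 2.55 h / 1.38 h.

## Synthetic rendering

**FRAP traces.** ROI means average hundreds of myosins, so the trace
renderer uses the analytic expected curve plus artifacts rather than a
per-site realization: converted-ROI green recovers with the replaced
fraction, red decays with its complement; the green channel (converted
and reference ROI alike) carries a multiplicative photobleaching decay
(default 0.05 h⁻¹), the red channel an additive linear drift (default
−2×10⁻⁴ of the post-conversion level per minute — a slow instrumental
decay of the kind the correction value exists to remove); both channels
get additive Gaussian noise (default sd 2% of the channel level; a
read-noise-dominated confocal assumption — a Poisson option was judged
unnecessary at this noise scale). One pre-conversion frame is prepended
10 min before the first post frame.

**Line scans.** Every myosin contributes a Gaussian of width
`psf_sigma` (default 0.1 µm) at its axial position in its label's
channel, sampled at `pixel_size` (default 0.05 µm) over one sarcomere
plus a 0.3 µm margin. The filament is tiled at ±1 sarcomere so the
green profile has genuine minima at the Z-bands — without neighbours
there is nothing for turning-point detection to find. Background (5%)
and noise (2%) are scaled to the peak of the combined green+red signal,
i.e. both channels share one intensity gain. No 3-D PSF or optical
sectioning.

**Labeling protocols.** Photoconversion flips incorporated label
green→red at the event (per site with probability
`conversion_efficiency`; the pipeline uses 0.9 — incomplete conversion
is realistic and leaves the green waveform defined at t = 0) and
incoming label is green. Pulse-chase leaves incorporated label green
and makes incoming label red from the chase start.

## Trace normalization and fitting

Green: converted-ROI values are multiplied by reference(pre)/reference(t)
(the non-converted region carries the bleaching), then affinely mapped
so pre ↦ 1 and the first post-conversion frame ↦ 0. Red: the correction
value is minus the least-squares slope of the raw red signal over the
500–600 min window of elapsed time (for traces shorter than 600 min,
the final 100 min with a warning); `raw(t) + correction·t` is rescaled
so post ↦ 1 against the per-time-point non-converted red level as zero.
Time origin is the first post-conversion frame.

Both channels fit `FI(t) = Mf(1 − e^{−bt}) + c` by bounded nonlinear
least squares (Mf ∈ [0, 1.5], b ∈ (0, 100] h⁻¹, c ∈ [−0.5, 0.5]); the
red series is first mirrored to its change magnitude 1 − y so Mf is
always a positive change. Initialization: Mf₀ = range, b₀ from the
half-range crossing time, c₀ = y(0), with up to five rate-perturbed
restarts; flat series and rate-at-bound optima are flagged
unconverged. Group comparison is a two-sided Student's t-test on Mf or
t½ over converged fits (≥ 2 per group).

A known property of the red path: the 500–600 min window still carries
a small residual of the exponential itself, and at 2% noise the
11-sample slope estimate is itself noisy; both propagate as a gentle
ramp over the whole corrected trace. On seven-trace experiments this
reproduces a between-experiment SD of ~4 points of Mf — the same order
as the replicate scatter the procedure shows on real data — and is left
as-is rather than tightening the estimator beyond the stated procedure.

## Waveform extraction

Per scan, both channels are smoothed with a least-squares polynomial
(default degree 6, configurable 2–10; degree is a compromise between
capturing one peak with shoulders and ringing on the plateau). Turning
points (Z-bands) are sub-pixel roots of the green derivative with
positive curvature. Two robustness rules matter in practice: (i)
candidate peaks must rise above the lower half of the fitted range;
(ii) per side of a peak, the turning point is the *nearest minimum
among those within a depth band (10% of range) of that side's deepest
minimum* — Z-band valleys all sit near the profile floor, whereas
mid-sarcomere dips (polynomial ripple on a flat top, or the genuinely
M-shaped green waveform at intermediate photoconversion times) are
shallow and must not terminate the window. Among candidate peaks the
pair enclosing the most green area wins, and each turning point is
refined by the vertex of a local quadratic on the raw samples (±3 px).

Channels are then re-fitted within the turning-point window (the
single-sarcomere window, where a low-degree polynomial is faithful),
the straight line through each channel's values at the turning points
is subtracted, each channel is divided by its post-subtraction maximum
(clipping small negative ripple to 0), and x is mapped affinely with
the midpoint at 0 — the M-line is defined as the turning-point
midpoint, not the green argmax, for robustness to asymmetric staining —
and turning points at ±1. Waveforms are resampled on a fixed 201-point
grid (odd, so x = 0 is on-grid). The pre-normalization dynamic ranges
are kept on the waveform for downstream classification.

Difference profiles are d(x) = red(x) − green(x), clipped to [−1, 1];
maps average the (per-time-point, per-channel normalized) waveforms
across sarcomeres *before* differencing. Because each channel is
normalized to its own maximum, d compares shapes, not abundances.

## Classification

All eight category names follow the experiment; every numeric decision
boundary is this package's own and is recorded in each output:
center zone |x| ≤ 0.25, side zone |x| ≥ 0.40, both-sides balance ratio
0.60 (below it: "predominantly" the taller side), shape-similarity
(Pearson r of red vs green) ≥ 0.90 for random fashion, red dynamic
range < 0.15 of the green dynamic range for no incorporation, and peak
prominence ≥ 0.20 of the channel maximum. The cascade runs
no-incorporation → random-fashion → two-side patterns → one-side
patterns → center → random-fashion (low-confidence fallback).
Correlation was preferred over max|d(x)| for similarity because it is
far less noise-sensitive. Peak-shift records are |x_peak| for every
side-zone peak (both peaks of a two-sided waveform count separately; a
per-sarcomere mean is also derivable from the long table). Frequency
summaries compute proportions per myotube, then mean ± SE across
myotubes; histograms use 0.05-wide bins on [0, 1] and medians per time
point report the inward trend. No statistical test is attached to that
trend.

## The pulse-chase population preset

`tip_biased_paper` is a population preset: 80% of sarcomeres draw
tip-biased kinetics (k_c = 0.35, k_t = 6.0 h⁻¹, p = 2) and 20% a slow
center-weighted profile (k = 1.2 h⁻¹ at the M-line decaying linearly to
0 at the tips), each scaled by a lognormal rate multiplier
(σ = 0.5, unit mean) emulating sarcomere-to-sarcomere variability. The
mixture is the package's modelling choice for a feature a single
monotone profile cannot produce: with tips always exchanging fastest,
the cumulative red density peaks at the tips in every sarcomere and the
center pattern would never occur. A minority of center-inserting
sarcomeres whose red only clears the detection floor after tens of
minutes yields the observed dynamics jointly — side groups near 80%
throughout, the center share rising toward ~20% by 30 min, and
no-incorporation fading after the earliest chase time. The component
parameters were calibrated once against those design frequencies and
frozen. Whether the fast-exchanging fraction is spatially identical to
the tip region is not observable in ensemble FRAP; the presets tie them
together as a modelling choice.

Ground-truth categories are assigned by rendering each sarcomere's true
label state without noise and running the identical extraction and
rules on it; with noise off the end-to-end classifier therefore agrees
with truth exactly, and the noisy-default agreement (≥ 85%, typically
93–98%) measures pure noise sensitivity.

## Seeding and determinism

Every stochastic entry point takes one integer seed; populations and
pipeline stages derive independent substreams via `SeedSequence.spawn`,
so identical (configuration, seed) pairs give bit-identical arrays and
byte-identical CSVs. Derived seeds are reduced below 2³¹.

## Problem sizes

The default study conditions are those of the experiments being
emulated: 7 traces per FRAP group sampled every 10 min for 10 h;
pulse-chase populations of 150 sarcomeres in 6 pseudo-myotubes at 7, 15
and 30 min of chase; photoconversion waveform series of 7 myofibrils at
10-min intervals to 200 min. The shipped demo pipeline uses smaller
counts (3 traces, 24 sarcomeres) as a quick smoke configuration.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analysis relies
on — biphasic ensemble kinetics, spatially biased insertion, channel
artifacts, sampling noise, replicate structure — but not optical
realities such as myofibril curvature, focus drift, spectral bleed,
variable sarcomere length within a fibril, or segmentation ambiguity.
Passing tests therefore validate the estimators and their
implementation under the stated model, not performance on raw
microscopy; the classifier's decision boundaries in particular are
calibrated to rendered exemplars, and real data may need different
thresholds (all are exposed in `ClassificationRules`).
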