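# Methods

This note documents the models, defaults and numerical choices behind each
stage of `hyalkit`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Molecular-weight distributions

A distribution is a discrete grid of masses (kDa, strictly ascending) with
non-negative weights. Weights are interpreted as **mass per grid slice**
(stain intensity is mass-proportional), so

Mw = Σ wᵢMᵢ / Σ wᵢ,  Mn = Σ wᵢ / Σ (wᵢ/Mᵢ),  PDI = Mw/Mn ≥ 1.

No Jacobian correction is applied when the slices are gel pixels rather than
uniform mass bins: the pixel intensity already *is* the mass migrating into
that pixel, which is the quantity the formulas above need. Number-weighted
data (nanopore event counts) are converted with wᵢ ∝ nᵢMᵢ before the same
formulas apply. Masses are kept in kDa throughout; Da are converted once on
input.

## Gel densitometry

* **Background**: rolling-ball subtraction is implemented as a 1-D
  morphological grey opening (erosion then dilation with a flat window of
  width 2·radius + 1). The opening passes structure *wider* than the window
  and removes narrower peaks, so the window must exceed the width of the HA
  smear: the function default is radius 50 px (appropriate for sharp bands),
  while the analysis drivers use 300 px for the broad synthetic smears that
  span ~300–400 px. Output is clamped to [0, input].
* **Calibration**: piecewise-linear interpolation of log₁₀(MW) against
  migration distance through the ladder anchors — exact at every anchor and
  monotone by construction. A polynomial was rejected because it can
  oscillate between anchors and has no principled order here.
* **Truncation, not extrapolation**: pixels migrating outside the anchor
  range are excluded and their intensity fraction reported; extrapolated MW
  beyond the ladder is unreliable.
* **Noise floor**: `lane_to_mwdist` accepts an optional intensity floor
  (fraction of peak, default off). Mn is a harmonic mean and a handful of
  noise-level pixels calibrated to very low MW can collapse it; a floor just
  above the residual noise (the drivers use 5% of peak, ≈3σ of the 1%
  simulated noise) restores Mn/PDI with ~1% effect on Mw.
* Distance is 0-based pixels from the configured well row, increasing toward
  the gel front; lane profiles aggregate image columns by mean (sum
  available).

## Nanopore sizing

* **Filter**: zero-phase 4th-order Butterworth at 5 kHz (`sosfiltfilt`),
  unit DC gain. The acquisition-side 100 kHz Bessel is a property of the
  hardware being emulated, not re-applied in analysis.
* **Baseline/σ**: median and 1.4826·MAD of the (filtered) trace. Robust
  statistics are essential because the blockades themselves would inflate a
  mean/SD estimate; σ is estimated on filtered data, matching the data the
  detector sees.
* **Detection**: maximal runs with |i − baseline| ≥ kσ (default k = 5) on
  the blockade side (below baseline by default; direction configurable since
  the sign convention depends on the applied-voltage polarity), then a
  duration gate of 25 µs–2.5 ms. Indices are 0-based, half-open.
* **ECD**: integral of |i − baseline| over the *suprathreshold* samples only
  (an option integrates crossing-to-crossing for sensitivity analysis).
  1 pA·s = 1000 fC.
* **Calibration**: least-squares line in (log ECD, log MW) through the
  standards' mean ECDs; inversion is closed-form, with an extrapolation flag
  outside the standards' ECD range. The standards' own small polydispersity
  (1.001–1.035) is ignored.
* **Summaries**: per-event MWs are a number-weighted sample: Mn is their
  arithmetic mean, Mw = ΣMᵢ²/ΣMᵢ.

## Microrheology

* MSD is time- and ensemble-averaged over all tracks and start frames
  (overlapping pairs), 2-D (Δx² + Δy²).
* The diffusion fit is a pair-count-weighted least-squares line
  MSD = 4Dτ + b over frame lags 1–8 (0.0625–0.5 s at 16 Hz). The intercept
  absorbs static localization noise; restricting to early lags balances
  pair statistics against the growing variance and finite-track bias of
  long lags. A non-positive fitted D is flagged; no viscosity is emitted.
* η = k_BT/(6πrD). Defaults: T = 295.15 K (22 °C, the temperature stated
  for the companion viscometry; the imaging temperature is not stated) and
  bead radius 0.25 µm. The source protocol prints "0.5-nm" beads while
  naming a 0.5 µm product; this is treated as a typo for 0.5 µm diameter —
  both temperature and radius are configurable.
* Only a Newtonian viscosity is reported. Drift subtraction is available as
  an explicit preprocessing choice but off by default; the simulated data
  contain no drift.

## Immunoblot HC-HA

a.u. = HC(+)/PreIαI(+) − HC(−)/PreIαI(−), with each HC band normalized by
the Pre-IαI band *of its own lane* (the formula is per-lane; the source text
is ambiguous on this point and the per-lane reading is adopted). Negative
values — possible from digestion/loading noise — are flagged but retained;
group summaries use medians, which are robust to this choice. Rows with a
non-positive normalizer are flagged per-row, never fatal to a batch.

## Cohort statistics

* **Gated test**: sample-skewness sign picks the transform (right-skew →
  cube root, left-skew → log; per-variable overrides available); if both
  groups pass Shapiro–Wilk at α = 0.05 after transformation, an unpaired
  t-test on the transformed values with means ± SEM, otherwise Wilcoxon
  rank-sum with medians ± IQR. Rank-sum p-values are invariant to these
  monotone transforms. The rank-sum uses the exact null for groups ≤ 20
  without ties, the tie-corrected normal approximation otherwise. The
  simulated null rejection rate at α = 0.05 is calibrated to [0.03, 0.07].
* **ΔΔCT**: ΔCT = CT_gene − CT_ref; the anchor is the healthy group's
  *median* ΔCT (so the healthy median fold change is exactly 1.0), with the
  healthy mean available as an option — the source describes both
  conventions and they are not identical.
* **5PL**: y = a + b/(1 + (x/c)^d)^f fitted by Levenberg–Marquardt with a
  deterministic multi-start over (d, f) ∈ {0.5, 1, 2, 4} × {0.5, 1, 2},
  because the two shape parameters trade off and a single start can stall.
  Inversion is closed-form; responses at or beyond the asymptotes are
  censored with a range flag rather than inverted.
* **Constrained quadratic**: under B₀ = 1, B₁ = 0 the least-squares solution
  is closed-form, B₂ = Σxᵢ²(yᵢ−1)/Σxᵢ⁴; R² = 1 − SS_res/SS_tot is reported
  as-is (it may be ≤ 0 for a poorly fitting constrained curve).
* **Flooring**: zero (undetectable) concentrations are replaced by a caller-
  supplied floor that must sit below the assay's detection limit; negative
  inputs are rejected.
* No multiple-testing correction is applied by default, matching the
  analysis being reproduced; Benjamini–Hochberg can be enabled downstream.

## Synthetic data

All generators draw from a single `default_rng(seed)`; identical arguments
give bit-identical outputs, and every generator returns a truth record.

* **MW distributions**: a mass-weighted log-normal hits target (Mw, PDI)
  exactly in the continuum limit via σ² = ln PDI, μ_w = ln Mw − σ²/2.
* **Gel lanes**: each pixel receives the cumulative mass between its edge
  MWs (so recovery is grid-exact before noise), plus a flat baseline and
  additive Gaussian noise scaled to the peak. The synthetic ladder spans
  10–50 000 kDa over 700 px so that high-Mw log-normal tails stay inside the
  calibrated range; real ladders are narrower, and with them the truncation
  behaviour (excluded-fraction reporting) becomes the relevant output.
* **Nanopore traces**: Poisson-arriving rectangular blockades; MW drawn
  number-weighted from the target distribution, ECD from the calibration's
  forward map, duration uniform in [50 µs, 2 ms] with the depth kept ≥ 6σ
  (or pinned at a requested SNR). Placements closer than 0.5 ms — which the
  5 kHz filter could not resolve — are redrawn. Rectangles make the ECD
  analytic; a raised-cosine edge option exists for filter-interaction
  studies. Real events have substructure and 1/f noise that this generator
  deliberately omits.
* **Brownian tracks**: per-axis Gaussian steps with sd = √(2DΔt), D from
  Stokes–Einstein; defaults emulate three 30-s videos of ~15 beads at 16 Hz
  (45 tracks × 480 frames). Optional localization noise inflates the MSD
  intercept, not the slope.
* **Cohort**: each variable is log-normal matched to its configured group
  median and IQR (σ = asinh(IQR/2·median)/z₀.₇₅). Variables whose reported
  healthy median is 0 are modelled as censored log-normals (values below a
  detection limit recorded as 0), since a literal zero median cannot come
  from a positive continuous law. Viscosity is generated from HA
  concentration through y = 1 + B₂x² (B₂ = 434 OA / 256 healthy) times
  log-normal noise (σ = 0.15). Default group sizes 25/61.
* **Blot tables**: Pre-IαI densities vary per lane; the digested lane's HC
  carries the sample's true a.u. on top of a basal HC/Pre-IαI ratio of 0.3,
  so the noiseless round trip is exact.

Passing these tests shows the computational chain is correct and calibrated
under the stated noise models; it does not validate instrument-specific
artifacts (gel warping, pore clogging, bead-matrix interactions,
non-Newtonian synovial fluid) that real data add.

## Problem sizes

The default test and acceptance runs use: 20 gel lanes of ~700 px; one 25-s
nanopore trace at 200 kHz (~10³ events); five viscosity conditions of
45 tracks × 480 frames; 1000 null simulations of n = 20 + 20 for the gated
test; and an 86-sample cohort — sizes chosen to match the study conditions
while keeping each stage's recovery variance a small fraction of its
tolerance.
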