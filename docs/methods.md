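# Methods

## Sensor model

The fruit battery is modelled as an ideal EMF `v_i` (volts) in series with an
internal resistance `r_i` (ohms); the measured quantity is the voltage across
an external load `r_l`,

    V_L(r_l) = r_l / (r_i + r_l) · v_i.

The model carries the standard divider properties used throughout the
analysis: V_L is strictly increasing in `r_l`, equals `v_i/2` at the matched
load `r_l = r_i`, and saturates at `v_i` for loads far above `r_i` — which is
why very large loads cannot discriminate ripe from unripe fruit: both
classes read ≈ `v_i` regardless of `r_i`.

Class separation at a load is quantified by
`|d_VL| = |(V̄_ripe − V̄_unripe)/V̄_unripe| × 100%`, applied to **class means**
(per-fruit replicate means first, then the mean over fruit of each class),
not averaged over per-pair differences. Only ripe and unripe fruit enter the
sweep; under-ripe fruit are excluded from load determination.

Load selection is two-stage: loads with `|d_VL| ≥ dvl_floor` (default 70%)
form the shortlist; among them the load whose moisture calibration has the
smallest |slope| in %/mV wins (a smaller slope means one mV of voltage change
spans less moisture, i.e. finer resolution). Ties break to the smallest
resistance — an arbitrary but deterministic convention, since real sweeps
essentially never tie. "Highest resolution" is interpreted throughout as
*smallest* %/mV, consistent with the < 1 %/mV acceptability criterion.

## Moisture analysis

Ripeness is a partition of moisture content: ≤ 30% ripe, (30, 53]% under-ripe,
> 53% unripe. Both boundaries belong to the lower class; 30% is explicitly
ripe. Inputs outside [0, 100]% are rejected.

Calibration regresses moisture (%, response) on load voltage (mV, predictor)
by ordinary least squares, so the slope is directly in %/mV. The regression
direction matters: the inverse fit would report mV/% and could not be
compared against the 1 %/mV criterion. A constant-response fit returns slope
0 with R² = 1 (the horizontal line is exact); a constant-predictor design
raises a degenerate-design error.

ADC arithmetic: a `b`-bit converter at drive voltage `V` steps in
`V / 2^b` volts; 12 bits at 3.3 V gives 0.80566 mV, displayed to one decimal
as 0.8 mV. Moisture resolution per count is |slope| × step; the sensor chain
is flagged acceptable when |slope| < 1 %/mV.

## Color correction and feature

The correction model is affine in RGB: each pixel `(R, G, B)` maps to
`a·(R, G, B, 1)ᵀ` with `a` a 3×4 matrix fitted per output channel by least
squares over the 16 chart chips (16 equations, 4 unknowns per channel). Chip
colors are sampled as the mean over the central 60% of each chip cell —
tolerating edge bleed — with the cells mapped into the image through a
supplied 3×3 homography. Live marker detection is deliberately out of the
core: any pose estimator can provide the homography, and pre-registered
images use the identity. A rank check on the observed-chip design matrix
rejects degenerate charts (e.g. all chips washed out to the same color).

Order of operations for the feature: **correct first, then segment, then
average**. Segmentation thresholds all three channels at 90 (a pixel is
background when R, G and B all exceed it), and thresholding the corrected
image keeps that rule meaningful across lighting conditions. The feature is
R_ave/G_ave with averages over foreground pixels only; averaging zeroed
background pixels would make the feature depend on how much background is in
the frame, i.e. on framing rather than on the fruit. Both denominators are
nevertheless implemented (`foreground_only` flag) since the all-pixel
convention is a defensible reading of the average-pixel formula.

Pixel arithmetic stays in floating point; clipping to [0, 255] happens when
a transform is applied and rounding to 8-bit only on image export.

## Classification protocol

The grid is the Cartesian product cost {1, 10, 100} × gamma {1, 0.1, 0.01} ×
kernel {linear, rbf}, 18 configurations, enumerated cost-major for
deterministic table order. Scoring is stratified, seeded, shuffled 8-fold
cross-validation; 52 samples over 8 folds leave 6–7 per fold, and without
stratification folds regularly lose a class entirely. Features are
standardized per training fold (the battery feature is tens of mV, the color
ratio is ≈ 1; a shared gamma grid presumes comparable scales). Gamma is
carried in linear-kernel rows for table completeness but does not affect a
linear SVM — which is why linear rows duplicate across gamma. The
fold-accuracy standard deviation uses the population convention (divide by
k); a `std_ddof` flag switches to the sample convention. Best-row selection
maximizes accuracy, breaks ties by minimum standard deviation, and remaining
ties by grid order. If a training split lacks a class the SVM is fitted on
the classes present and a warning is issued.

## Synthetic-data generator

The generator emulates the statistical structure of a 52-fruit field study
(21 ripe / 15 under-ripe / 16 unripe by default):

* moisture is uniform within each class band — ripe 24–30%, under-ripe
  30–53%, unripe 53–80.1%, spanning the reported composition extremes of
  ripe and unripe mesocarp;
* the moisture-to-circuit link is an assumed linear voltage line at the
  1 kΩ calibration load, `V_L(mV) = −25 + 1.9·moisture`, inverted through
  the divider to `r_i = r_cal·(v_i/V_L − 1)` with lognormal fruit-to-fruit
  scatter (σ = 0.1). No parametric `r_i(moisture)` law is established
  empirically; this construction is a modelling assumption chosen because it
  reproduces, simultaneously, the three behaviours the analysis relies on:
  an approximately linear moisture–voltage scatter at 1 kΩ with slope
  ≈ 0.53 %/mV, a ripe/unripe |d_VL| plateau of ≈ 74–77% across 10 Ω–1 kΩ
  that decays at higher loads (≈ 59% at 10 kΩ, ≈ 3% at 1 MΩ), and 1 kΩ as
  the only load with sub-1 %/mV resolution. The intercept is the binding
  choice: mild intercepts flatten the class contrast to ≈ 50–55% and no load
  clears the 70% floor;
* each (fruit, load) voltage is read three times with 1 mV additive noise
  (the order of the prototype's ADC step) and the replicates averaged;
* the EMF is constant 0.9 V by default with optional lognormal jitter — the
  true EMF distribution across fruit is unknown;
* the color feature decreases affinely from 1.8 (24% moisture) to 0.9
  (80.1%), with Gaussian noise σ = 0.08 — set once so the vision modality's
  cross-validated accuracy sits in the high-80s band reported for color
  features, and independent of the battery noise so combining modalities can
  help;
* photographs are a bright background (235), a 4×4 chart of 16 reference
  colors, and an elliptical fruit whose channels `(ratio·70, 70, 40)` give
  the sample's true R/G exactly. Chip reference values live in [100, 195]:
  above the background threshold, so after correction the chart removes
  itself from the foreground; below the level where realistic illumination
  gains (0.8–1.1 plus ±0.04 cross-talk and ±10 offsets) would clip at 255.
  The blue channel of 40 keeps fruit pixels failing the background rule
  under any such illumination; a contamination flag is set if an extreme
  user-supplied illumination ever pushes fruit pixels past it. Per-pixel
  Gaussian noise (default σ = 2 channel units) is switchable to zero for
  exactness tests.

What the generator does **not** emulate: spikelet texture and specularity of
real fruit bunches, non-affine camera processing (white balance, JPEG
compression), electrode placement variability, and any correlation between
EMF and ripeness. Tests passing on synthetic cohorts therefore validate the
*analysis machinery* — estimators, selection logic, protocol — not field
performance; the real study's per-fruit measurements are not public, so its
accuracy tables are reproduced as a protocol and an ordering property
(combined ≥ single modalities), never as target numbers.

## Numerical and design notes

* Errors-in-variables: measurement noise sits on the voltage (the regression
  predictor), so fitted slopes are attenuated slightly toward zero relative
  to the generator's structural slope 1/1.9 ≈ 0.526 %/mV; at the default
  noise the mean attenuation is ≈ 3%, within the 5% recovery tolerance the
  tests assert over 200 cohorts. OLS is retained regardless — it is the
  field's convention for this calibration.
* |d_VL| monotonicity in the load is exact in the noiseless construction;
  at 10 Ω true voltages are ≈ 1 mV, so with 1 mV replicate noise the 10 Ω
  statistic fluctuates by several points and only the noiseless property is
  strict.
* The |d_VL| shortlist floor (70%) is configurable; it sits just below the
  ≈ 74–77% plateau so the plateau loads shortlist and the decayed ones do
  not.
* Chip sampling uses polygon rasterization of the homography-mapped cell
  interior; a cell mapping even partly outside the frame is an error naming
  the chip, rather than a silently truncated mean.
* All seeds flow through `numpy.random.default_rng`; identical seeds give
  byte-identical CSV fixtures and manifests.

## Problem sizes

Default analyses run on the 52-fruit cohort (936 replicate readings across
six loads). Statistical properties are asserted over repeated cohorts: 200
seeds for slope recovery, 100 for correction-improves-chips, 50 for the
combined-versus-single-modality ordering; the full suite completes in about
two minutes on one CPU.
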