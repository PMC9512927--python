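# Methods

## The calibration model

Each mass channel of a survey scan is modelled as

    I = b + s·d + ε,    ε ~ (0, σ²),

with `d` the dilution factor of the external standard relative to the
undiluted main calibration mixture (`d = 1` undiluted, `d = 0` blank), `b`
the background intensity, `s` the sensitivity and `σ` an element-specific
error SD assumed independent of `d`. Three points are deliberate:

* **Straight line with intercept.** Linearity of ICP-MS response over the
  working range is the standard assumption; the intercept absorbs
  blank-borne signal and partly corrects interferences originating from the
  blank solution. Blanks (`d = 0`) are ordinary calibration points.
* **Dilution factor, not concentration, as the regressor.** Every channel
  then shares the same design vector, so the entire panel is fitted in one
  broadcast pass; the element's concentration `C0` in the main mixture
  enters only at the very end (`ĉ = r̂·C0`).
* **Unknown, homoscedastic error variance.** `σ` is a parameter, estimated
  per channel; no variance function (variance ∝ intensity) and no weights.

Estimation is closed-form ordinary least squares:

    ŝ = S_dI/S_dd,  b̂ = Ī − ŝ·d̄,  σ̂² = RSS/(n−2),
    var(ŝ) = σ̂²/S_dd,  var(b̂) = σ̂²(1/n + d̄²/S_dd),
    cov(b̂,ŝ) = −σ̂²·d̄/S_dd.

The unbiased `n−2` denominator was chosen over the maximum-likelihood `n`;
the definition is isolated in `fit_element_calibration` so it can be
swapped. At least 3 points are required (else σ̂ is undefined) and at least
two distinct dilution levels (else the slope is unidentifiable); ties are
allowed. A negative fitted sensitivity is retained in the Calibration File
but flagged, and inverse prediction refuses such channels.

The vectorized multi-channel fit runs the exact same numpy reduction
sequence as the scalar fit, so the two are bit-identical on designs of up
to 8 calibration points (beyond that numpy's pairwise summation can change
the rounding of the per-channel path); typical dilution series have 4–6.

## Inverse prediction and uncertainty

An assay intensity `I` (mean of `m` replicates) inverts to
`r̂ = (I − b̂)/ŝ` and `ĉ = r̂·C0`, with first-order (delta-method)
propagation

    sd(r̂)² = (σ̂²/m + var(b̂) + r̂²·var(ŝ) + 2·r̂·cov(b̂,ŝ)) / ŝ².

The sample intensity's own error uses the calibration-estimated σ̂ of the
channel (survey exports carry no per-sample replicate SD); the calibration
estimates and the sample intensity are treated as independent, while the
b̂–ŝ covariance is kept. `C0` is treated as exact (certificate uncertainty
of the reference materials is not propagated). For a valid covariance
matrix the bracket is bounded below by σ̂²/m, so the defensive clip-to-zero
branch can only trigger on externally supplied calibration files that
slightly violate the Cauchy–Schwarz bound.

Conventions that preserve downstream statistics:

* Negative `ĉ` is reported as-is and flagged `below_background`, never
  truncated — truncation would bias run averages of blank-level channels.
* `r̂ > 1` is allowed and flagged `extrapolated_above_standard`; the
  response remains linear above the top standard and such results carry
  small relative SDs.
* Pooled ("time-averaged") concentrations average the survey intensities
  first and invert once. By linearity the point estimate equals the mean of
  per-sample estimates; the SD correctly carries the σ̂²/m pooling gain.
* Elements are reported from their designated primary isotopic channel;
  estimates from secondary channels are retained in the Concentrations File
  and marked as such.

### Coverage: t, not normal

With a five-level dilution series measured once per level, σ̂² has only
n − 2 = 3 degrees of freedom, and every term of sd(r̂) scales with σ̂. The
pivot (r̂ − r)/sd is therefore Student-t with 3 df, not normal:
P(|t₃| ≤ 1.96) ≈ 0.855, so "±1.96 sd" intervals cover ~85% rather than
95%, a ±3 sd acceptance band holds ~94% rather than 99.7% of the time, and
a "keep if ĉ exceeds its sd" screen keeps a null element ~7% rather than
~2.6% of the time. None of this is a defect of the propagation — the sd is
accurate — it is the heavy tail of estimating a variance on 3 df.
`CalibrationResults.conf_int()` therefore uses t-quantiles on n − 2 df and
achieves nominal coverage; anything downstream that applies normal-theory
multiples to the reported sd inherits the t-tail. With more calibration
points (or replicated standards) the distinction disappears.

## Screening

Two survey runs (e.g. two culture media measured on separate occasions,
with different standard mixtures) are compared in three steps:

1. quantify everything present in each run's standards;
2. intersect the two element panels; elements outside the intersection are
   `excluded_not_common`;
3. exclude elements whose estimated SD is in the range of the estimated
   concentration. This is operationalized per run as
   median(sd) ≥ ρ·|median(ĉ)| or median(ĉ) ≤ 0 over the run's samples,
   with ρ = 1 by default. Median was chosen as the run-level summarizer
   (robust to single below-background samples); both ρ and the summarizer
   are configurable because no numeric rule is canonical.

Surviving elements with a peak-hopping counterpart are validated through
z = (ĉ_CC − c_PH)/sd_CC with the usual |z| ≤ 3 criterion. Only the
compressed-calibration SD enters (peak-hopping uncertainties are assumed
negligible by comparison); no multiple-testing correction is applied.

## Time-series metrics

* **Time-averaged concentrations** — pooled-intensity quantification over a
  condition's samples (above).
* **Last-minus-first change** — Δ = ĉ_last − ĉ_first,
  sd_Δ = √(sd_last² + sd_first²), the two samplings being independent.
* **Relative deviation between treatments** — per shared timestamp,
  ρ_t = (ĉ_BS − ĉ_BA)/ĉ_BA with delta-method SD; positive means
  biostimulation exceeds bioaugmentation. The denominator convention is one
  configurable function; series are compared on the intersection of their
  timestamps (no interpolation — sampling schedules are irregular), and a
  non-positive reference yields a flagged NaN.
* **XRF normalize-to-last** — each relative-abundance series divided by its
  final value (used when the first measurement is below detection limit);
  idempotent, final element exactly 1.

## The synthetic-data generator

`simulate_design`/`simulate_survey` emulate the structure of a column
bioleaching experiment monitored by ICP-MS survey scans, so every stage is
testable without external data:

* one run per culture medium; assay layout = {BS, BA} × {effluent, pore}
  × 5 sampling days (effluent days 2, 9, 12, 16, 19; pore-water days 3, 5,
  8, 10, 17); calibration series {1, 0.5, 0.1, 0.01, 0}, one sample per
  level;
* a 9-element default panel (Mg, Si, Al, K, Mn, Fe, Cu, Zn, Se — the
  interfering-component panel) extensible to 50 elements, channels chosen
  as each element's most abundant isotope;
* per channel: sensitivity log-uniform over 10³–10^5.5 cps per unit d,
  background 5–30% of the top-standard signal, error SD 0.3–1.5% of the
  sensitivity (survey-mode counting noise is sub-2% at the top standard;
  backgrounds of a few to tens of percent reflect blank-borne signal).
  Mixture concentrations C0 log-uniform over 10–1000 µg/L;
* assay truths follow smooth exponential time trends per condition; the
  panel always includes one element leached beyond the main standard
  (true r* = 1.5 scale, exercising the extrapolation flag) and one with
  true concentration exactly zero (exercising the significance screen);
* noise is Gaussian, i.i.d. within a channel, variance independent of the
  dilution factor — the model's own assumption. The distribution is a
  generator argument, so Poisson-like count noise can be plugged in later.
  Draws are floored at zero after noise (counts are physical) and the
  flooring events counted, since flooring biases blank-level channels; at
  the default noise levels flooring is absent or negligible;
* one master seed; per-channel substreams are spawned deterministically, so
  growing the panel never perturbs existing channels' draws.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: matrix effects and polyatomic
interferences (beyond what the background intercept absorbs), instrument
drift between standards and assays, detector dead time, isobaric overlap
between panel elements, and non-Gaussian count statistics at very low
intensities.

## Numerical choices and edge cases

* Fits and inversions are plain float64 closed forms; no iterative
  optimization anywhere.
* CSV round trips are exact: floats are written in shortest round-trip
  representation and parsed with round-trip precision.
* Degenerate designs fail loudly: < 3 points, or a single distinct
  dilution level, are errors, as is a calibration-role sample without a
  declared dilution factor.
* Zero sd in the cross-method comparison: z = 0 (pass) when the
  concentrations agree exactly, ±∞ (fail) otherwise.
* Mass-channel labels (`27Al`) are validated against the NIST isotope
  table; an unmapped channel falls back to the element parsed from its own
  label, and channels of elements absent from the standard mixture are
  dropped at the survey split.

## Problem sizes

The test suite and `scripts/acceptance.py` use: 200 random designs of 3–10
points for the least-squares oracle; 2,000 replicates for coverage; 10⁶
draws for Monte-Carlo propagation; 500 replicates × 100 samples for the
screening rates; 1,000 replicated 9-element surveys (180,000 pairs) for
the cross-method pass rate; and a 50-channel survey for the vectorization
identity. Everything completes in well under a minute on one CPU.

## Known limitations

* External calibration without an internal standard: vulnerable to matrix
  effects and drift; nothing here corrects them post hoc.
* The homoscedastic-in-d error model understates uncertainty if variance
  actually grows with intensity; a variance-function calibration is out of
  scope.
* Symmetric delta-method intervals; Fieller-type inverse-prediction
  intervals are not implemented.
* With 3 residual df, normal-theory multiples of the reported sd
  undercover (see above); use `conf_int()` or t-quantiles.
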