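# compcal — post-measurement compressed calibration for ICP-MS survey scans

ICP-MS runs routinely record a preliminary *survey scan*: low-precision
intensities for every measurable mass channel, acquired before the precise
peak-hopping measurement of the handful of analytes chosen in advance.
`compcal` turns those survey intensities into quantitative concentrations
— with standard deviations — for **every element present in the external
calibration standards**, entirely after the fact. No re-measurement, no
internal standard, no vendor semi-quantitative estimator. It was built for
monitoring non-target "interfering components" (Mg, Si, Al, K, Mn, Fe, Cu,
Zn, Se, …) leached from mine tailings in bioleaching column experiments,
but applies to any survey-scan dataset measured alongside a multi-element
standard dilution series.

## The model

For each mass channel, intensity is linear in the dilution factor *d* of
the external standard with respect to the undiluted main calibration
mixture:

```
I = b + s·d + ε,    ε ~ (0, σ²)
```

* `b` — background intensity (cps), absorbing blank-borne signal,
* `s` — sensitivity (cps per unit dilution factor),
* `σ` — element-specific error SD of intensity measurements, assumed
  independent of `d` and **estimated as a parameter** (σ̂² = RSS/(n−2)).

Using the dilution factor as the regressor makes the design matrix the
same for all channels, so the whole panel is calibrated in one vectorized
least-squares pass. An assay intensity `I` is then inverted to a
dilution-equivalent `r̂ = (I − b̂)/ŝ` and a concentration `ĉ = r̂·C0`,
where `C0` is the element's concentration in the main mixture. The SD is
first-order error propagation keeping the b̂–ŝ covariance:

```
sd(r̂)² = (σ̂²/m + var(b̂) + r̂²·var(ŝ) + 2·r̂·cov(b̂,ŝ)) / ŝ²
```

with `m` the number of intensity replicates averaged into `I`. Downstream
tools screen elements whose SD is in the range of the estimate, validate
against peak-hopping results at the 3-SD level, and compute leachate
time-series summaries (time averages pooled at the intensity level,
last-minus-first changes, BS-vs-BA relative deviations, XRF
normalize-to-last).

## Worked example

```python
import compcal as cc

design, truth = cc.simulate_design(n_elements=9, seed=42)   # known ground truth
survey = cc.simulate_survey(truth, seed=42)

model = cc.CompressedCalibration(survey, design)
res = model.fit()
print(res.summary())
```

```
Compressed calibration fit
==========================
calibration samples : 5
dilution levels     : 1, 0.5, 0.1, 0.01, 0
assay samples       : 20
channels retained   : 9

 channel elem   C0 ug/L      bg cps      (se)   sens cps/d       (se)   resid sd
    24Mg   Mg     12.24      9818.9       604      86409.8    1.2e+03       1036
    28Si   Si     20.35      1179.7      76.1        12670        152      130.6
    27Al   Al     232.3       37477  1.07e+03       138341   2.13e+03       1835
     ...
```

Each row is one fitted calibration line: the background `b̂` and
sensitivity `ŝ` with their standard errors, and the estimated noise SD of
that channel. Averaging a condition's survey intensities first, then
inverting once, gives run-averaged concentrations with the pooled SD:

```python
ids = [s for s in model.assay_part.sample_ids if "BS_effluent" in s]
print(res.quantify_mean(sample_ids=ids, label="BS effluent (time-avg)"))
```

```
             sample_id element  concentration   sd                        flag
BS effluent (time-avg)      Mg           0.58 0.10                          ok
BS effluent (time-avg)      Si           2.45 0.14                          ok
BS effluent (time-avg)      Al         370.15 4.95 extrapolated_above_standard
BS effluent (time-avg)       K          54.14 1.27                          ok
...
```

Concentrations are in µg/L (`unit="ppm"` rescales to mg/L). Al exceeds its
concentration in the main standard (`r̂ > 1`, flagged but still precise —
the response stays linear above d = 1); Se here is a trace detection whose
SD is in the range of the estimate, exactly what the significance screen
(`cc.significance_filter`, `cc.screen`) excludes from further analysis.

The same pipeline is scriptable from the shell:

```sh
compcal simulate  --seed 42 --elements 9 --out data/
compcal calibrate --survey data/survey_intensities.csv --standards data/standards.yaml --out out/
compcal quantify  --survey data/survey_intensities.csv --standards data/standards.yaml \
                  --calibration out/calibration.csv --out out/
compcal screen    --cc out/concentrations.csv --ph peak_hopping.csv --out out/
```

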