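# gedikit

Single-cell quantification of radiation-induced death and DNA damage in
glioma cultures, built around a genetically encoded death indicator (GEDI):
a dual-fluorescence biosensor pairing a green calcium sensor (GC150) with a
constitutive red morphology marker (mApple). Lethal calcium influx raises
the per-cell **GEDI ratio** — mean green over mean red fluorescence — past a
calibrated threshold, marking apoptotic commitment independently of bulk
viability assays that extracellular vesicles are known to confound.

The package is a library for scientists analysing (or prototyping analyses
of) such experiments. It provides, end to end:

- **a synthetic-data generator with ground truth** — time-lapse biosensor
  stacks with exponential, dose- and sEV-dose-dependent death hazards,
  DNA-damage focus images with Poisson counts under an
  induction-plus-repair rate law, flow-cytometry event tables, and growing
  colony series — so every downstream stage can be validated against known
  truth;
- **image operations**: rolling-ball background subtraction (grayscale
  opening with a ball structuring element), optional Richardson–Lucy
  deblurring, threshold segmentation into labelled masks, per-cell
  intensity measurement and GEDI ratios, and puncta detection as local
  maxima an order of magnitude above each cell's own background;
- **the GEDI pipeline**: threshold calibration as the geometric mean of the
  baseline and post-lethal-dose (25 Gy) ratio medians, greedy
  nearest-centroid tracking, and fate classification — a cell dies at its
  first ratio crossing or at disappearance from the field (detachment),
  whichever comes first, and is otherwise censored at the horizon;
- **survival statistics from first principles**: the Kaplan–Meier
  product-limit estimator S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i), the two-sample
  log-rank test, and one-/two-way ANOVA (type-II sums of squares) with
  Tukey HSD;
- **ancillary assays**: 53BP1/γ-H2AX focus time courses, clonogenic
  colony-area growth fitting, and flow-cytometry positivity gating above
  the 99.5th percentile of an unstained control.

## Worked example

`examples/gedi_survival_demo.py` simulates a four-arm experiment (control
plus three vesicle doses that scale the 8 Gy death hazard by 0.7/0.5/0.4),
calibrates the threshold, tracks and classifies every cell, and prints:

```
irradiation: 8 Gy at 4.82 Gy/min -> 1.66 min exposure
calibrated GEDI threshold: 1.040 (live median 0.523, dead median 2.071)

Kaplan-Meier survival at 18 h post-irradiation:
  control (0 sEV/cell)     S(18h) = 0.173 (true exponential: 0.165)
  low (2500 sEV/cell)      S(18h) = 0.280 (true exponential: 0.284)
  medium (5000 sEV/cell)   S(18h) = 0.433 (true exponential: 0.407)
  high (15000 sEV/cell)    S(18h) = 0.453 (true exponential: 0.487)

log-rank vs control (protection should grow with dose):
                 group                   vs      chi2      p_value
   low (2500 sEV/cell) control (0 sEV/cell) 12.838226 3.396095e-04
medium (5000 sEV/cell) control (0 sEV/cell) 29.335916 6.085723e-08
 high (15000 sEV/cell) control (0 sEV/cell) 37.163415 1.086328e-09
```

The calibrated threshold sits at ~1 (the reporter's operating point: live
and dead ratio medians of 0.5 and 2.0 are reciprocal), the per-arm
Kaplan–Meier estimates track the generating exponential survival curves,
and the log-rank chi-square grows monotonically with vesicle dose —
dose-dependent protection recovered from raw pixels.

The other examples exercise one capability each and print the analogous
truth-vs-measured comparison: `foci_kinetics_demo.py` (focus counts rise
from baseline by 3 h after 4 Gy and decay back with a 4 h repair
half-life), `flow_gating_demo.py` (95% and 30% labelled fractions
recovered within fractions of a percentage point), and
`colony_growth_demo.py` (fitted log-area slopes within a few percent of
ln 2 per frame for doubling colonies).

A thin CLI wraps the same pipeline for shell use:

```sh
gedikit duration 8                 # 1.66 (minutes at 4.82 Gy/min)
gedikit gedi -c config.yaml -o runs/demo
gedikit all --seed 3 -o runs/full
```

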