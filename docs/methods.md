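# Methods

This note documents the models behind `gedikit`: what the simulator
generates, how each quantification stage works, the defaults and why, and
what the validation does and does not establish.

## The death-assay model

Cells carry a ratiometric death reporter: a red morphology marker of
constant per-cell amplitude and a green calcium channel whose amplitude is
a per-cell multiple of the red one. The green/red ratio is lognormal
around a **live median of 0.5** before death and a **dead median of 2.0**
after (spread `ratio_sigma_log = 0.25`); these reciprocal medians place
the natural classification threshold at 1, the reporter's operating
point. Death is a step: at the cell's death time the green amplitude
jumps from the live to the dead level — the simplest model consistent
with an irreversible loss of membrane calcium homeostasis — and after a
**detachment delay (default 4 h)** the cell leaves the field of view.

Death times are exponential with hazard

    λ = base_hazard × protection_factor × dose/8 Gy + spontaneous_rate.

The base hazard (0.1/h at the 8 Gy reference) gives ~17% control survival
at the 18 h horizon, matching the qualitative extent of death visible in
the source experiments; the linear dose scaling is the minimal choice in
the absence of a stated dose–response and is a configuration knob, with a
small spontaneous rate (0.002/h) so unirradiated cultures are not
perfectly immortal. Protection factors below 1 model vesicle-mediated
hazard reduction; the default arms use 1 / 0.7 / 0.5 / 0.4 for 0 / 2500 /
5000 / 15000 vesicles per cell.

Rendering: cells are 2-D Gaussian blobs (σ = radius/2, default radius
8 px at 20X-like scale) placed by rejection sampling at ≥ 2·radius + 4·
motion-sd separation, moving by a Gaussian random walk (sd 2 px/frame) —
enough to exercise tracking without ambiguity. Images get a flat camera
offset (10 a.u.), Poisson shot noise (gain 0.5) and Gaussian read noise
(sd 2). A single seeded generator drives every draw in a documented
order, so a fixed config is bit-reproducible.

## Quantification of the death assay

Each frame is background-corrected before measurement (median subtraction
by default — exact for the simulator's flat background and the rolling-
ball limit for one; the full morphological estimate is available). Masks
come from the red channel: Otsu threshold (or manual), 4-connected
labelling, minimum object area 20 px. Otsu always produces *some* split,
so the automatic mode carries a bimodality guard (mean foreground ≥ 2×
mean background, configurable) that declares blank noise images empty
rather than reporting percolation clusters of supra-threshold noise.

Per-object measurements (unweighted centroid, area, channel means, the
green/red ratio; zero-red objects are flagged and excluded) are linked
frame to frame by greedy nearest-centroid matching in ascending distance
order with a 30 px displacement budget. Unmatched previous-frame tracks
terminate with a disappearance timed at the midpoint of the bracketing
interval; disappearance is scored as a **death** (detachment follows
death in this assay), not as censoring. Ratio crossings take the frame
time of first exceedance (right-endpoint convention). A cell with
neither event by the horizon is censored there. With the default
generator settings the classified death indicator at each frame time is
essentially exact, so pipeline error is dominated by segmentation edge
cases rather than timing bias.

Threshold calibration mirrors the experimental procedure: measure ratios
in an unirradiated baseline acquisition and in a lethal-dose (25 Gy)
acquisition 24 h later in which every cell is dead but still attached,
then take the **geometric mean of the two group medians** — symmetric on
the log-ratio scale and equal to 1 for reciprocal medians. Calibration
requires ≥ 30 cells per group and a dead median strictly above the live
median.

## Survival statistics

Kaplan–Meier and the log-rank test are implemented from first principles
(the package's statistical core) and cross-checked in the test suite
against lifelines and against a label-permutation null. Ties follow the
standard convention: deaths are processed before censorings at equal
times. Only the point estimate and counts are promised — no Greenwood
confidence bands. Multi-arm experiments are reported as pairwise
log-rank tests against the control arm without multiplicity adjustment
(matching per-curve reporting practice); a Bonferroni option exists but
is off by default.

ANOVA is one-way, or two-way with interaction using type-II sums of
squares (each main effect against the model containing the other, the
interaction against the additive model), computed via least-squares
design matrices; Tukey–Kramer comparisons use the studentized range on
(marginal) level means with the full-model mean square. statsmodels
serves as the oracle in tests, never as the implementation.

## DNA-damage foci

Per cell and timepoint the true focus count is Poisson with rate

    baseline                                          (t = 0)
    baseline + induction·dose · 2^(−t/halflife)       (t > 0).

The t = 0 frame is imaged at irradiation, before foci have assembled, so
it carries the baseline only; counts therefore peak at the first
post-irradiation frame and decay back as breaks are repaired. Defaults:
baseline 1 focus/cell, induction 3 foci/Gy (≈ 12 foci at the 4 Gy dose
used for damage kinetics), repair half-life 4 h — which reproduces the
observed rise-by-3-h, return-by-20-h shape on the 0/3/9/20 h imaging
grid. Note the law never reaches baseline exactly; at 20 h about 3% of
the induced signal remains, which is why the "returned to baseline"
validation is an equivalence bound (residual below 13% of the peak
elevation at 99% confidence) rather than a no-difference test that any
sufficiently large sample would fail.

Foci render as narrow Gaussian peaks (σ = 0.8 px, ≥ 5 px apart) inside
disk-shaped cells (radius 20 px for focus assays — foci are
diffraction-limited and small relative to the cell, which keeps the
median background estimate uncontaminated even at ~13 foci/cell). Each
focus is normalized so its brightest **rendered pixel** sits at
`puncta_amplitude_fold` (default 12) times the cell's own background;
without that normalization, subpixel centres drop up to
exp(−0.5/2σ²) ≈ 32% below the nominal peak and a 10× detector misses a
fifth of 12× foci by construction.

Detection operationalizes "an order of magnitude above background":
per-cell background is the median intensity inside the mask after one
refinement pass excluding pixels above 10× the initial median; puncta are
local maxima ≥ 10× that background, non-maximum-suppressed at 3 px.
Live 53BP1-style assays carry body and foci in one reporter channel, so
masks are segmented from a median-filtered copy (5 px window suppresses
the puncta, leaves the body plateau); fixed γ-H2AX-style assays segment
nuclei from DAPI and detect in the green channel, at the 4 h
peak-accumulation timepoint by default. On simulated data at the 12×
amplitude the per-cell counts are recovered essentially exactly
(≥ 95% of nuclei exact; count-level recall and precision > 0.97).

## Colonies and flow cytometry

Colony series: flat disks whose true area grows exponentially per imaging
day. Quantification per frame is rolling-ball subtraction → threshold →
label → area; colonies link across days by nearest centroid, and growth
is the least-squares slope of log-area on frame index (ln 2 per frame for
doubling colonies; recovered within a few percent, the residual coming
from pixel discretization of disk areas). The rolling-ball radius must
exceed the largest colony radius or the ball "climbs onto" the plateau
and erases it; the colony stage defaults to radius 35 px on a 256 px
field for that reason.

Rolling ball itself is the classic estimate: grayscale opening with a
non-flat ball structuring element (height profile √(r²−d²)), computed
with edge-replicated erosion/dilation and verified against brute-force
min/max loops. Richardson–Lucy deblurring (optional, off by default — the
vendor software's deconvolution parameters are unknown, so it is excluded
from validation) uses edge-replicated convolutions, making a flat image
an exact fixed point and conserving interior flux to ~1%.

Flow cytometry: stained events are a lognormal mixture (negative median
100 a.u., positive median 1000 a.u., σ_log 0.3 — a 10-fold separation);
the positivity gate is the **99.5th percentile of the unstained
control** (the stated procedure fixes only "above the unstained gate";
99.5 is this package's default and is configurable). By construction
~0.5% of a purely negative sample gates positive, so a 30% true fraction
reads ~30.35% — well inside the reported tolerances. MFI is the
arithmetic mean (cytometry convention), with a geometric option.
Scatter channels and the singlet flag are pass-through filler: no
doublet, compensation or dye-dilution modelling.

## Validation scale and limitations

The acceptance-style tests run the full imaging pipeline at n = 300
cells/arm across 4 arms, replicated 10 times, and compare the
replicate-averaged Kaplan–Meier curves with the generating exponential
survival (±5 percentage points per arm and frame; a single replicate's
binomial sampling noise alone is ~3 points sd, so the average is the
meaningful estimator at this n). Log-rank power (p < 0.001 in ≥ 95% of
100 replicates at hazard ratio 0.4) is checked at the survival-record
level, and type-I error under the null over 200 simulations must fall in
[0.02, 0.09] at α = 0.05. Focus kinetics are validated at 220
cells/condition against Poisson bounds. These sizes keep the whole suite
in a few minutes on one core.

What passing does **not** show: the generator has no optics-accurate PSF,
no photobleaching, no cell division or mitosis-driven track splitting, no
gap-closing across missed detections, no touching-cell watershed (cells
are placed apart by construction), and flow events carry no spillover or
division peaks. Real microscopy violates several of these at once;
results here certify the quantification logic, not robustness to every
imaging pathology.
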