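# Methods

## Drusen morphometry

### Measurement model

The input is a pair of segmented boundary surfaces per eye and visit —
the Choroid/Bruch's-membrane (BrM) boundary and the RPE/photoreceptor-
outer-segment (RPE/POS) boundary — sampled on a complete rectangular
grid of B-scans × A-scans (defaults: 61 B-scans at 109 μm pitch, 512
A-scans at 17 μm pitch). Depths increase posteriorly in μm. Missing
grid samples are an error, never imputed: silent imputation would bias
heights near segmentation failures.

Thickness is the pointwise difference `T = z_BrM − z_RPE/POS`. Under
axial noise it may be transiently negative; values below −3× the stated
noise sd are flagged rather than clipped, because at that magnitude a
negative thickness indicates a segmentation fault, not noise.

### Detection

A drusen-free reference profile is estimated per B-scan by a running
median over `baseline_smoothing_window` A-scans. Two numerical choices
matter here:

* **Window width (default 61 samples ≈ 1 mm).** A running median rejects
  an elevation only when more than half the window is drusen-free. At a
  17 μm A-scan pitch, drusen a few hundred μm across contaminate 25–30
  samples, so a ~0.5 mm window sits on the druse's own shoulder and
  absorbs 20–40% of its height, which silently raises the detection
  threshold and shrinks footprints; 1 mm clears drusen up to ~500 μm
  across. The window is a `DetectionParams` field for other geometries.
* **Iterated masked median, mirrored edges.** The median is re-applied
  with samples elevated above the current reference replaced by it
  (until stable, at most 8 passes), removing the residual shoulder bias;
  edges are mirrored rather than replicated, since replicating a single
  noisy edge sample ~30× inside the window lets one low draw drag the
  reference down and manufacture spurious edge components.

Footprints are 4-connected components of `excess ≥ min_peak_height/2`
retained when their peak excess reaches `min_peak_height` (default
10 μm, ≈3.5 sd of thickness noise at the default 2 μm axial noise). A
footprint is *visible* — i.e. counted as a clear druse distorting the
RPE/POS boundary — when it spans ≥ `min_sections` B-scans (default 2)
and ≥ `min_footprint_ascans` A-scans in its widest section (default 3).
These thresholds operationalise a criterion that is applied visually in
practice; all are exposed in `DetectionParams`. Components are ordered
by centroid so detection output is deterministic.

### Heights

The height reference for a druse is the *flanking baseline*: thickness
averaged over the druse's A-scan span in the first B-scan before its
footprint and the first after it, averaged across the two. The same
pair serves every section of that druse. The flanking sections are
required to be free of the measured druse only, not of all drusen. A
footprint touching the first or last B-scan uses the available side and
is flagged `edge=True` instead of being excluded, keeping counts
conservative and auditable.

Per section, height = (mean thickness over the footprint's A-scans in
that section) − baseline, clipped below at 0; the average height is the
arithmetic mean of the per-section heights. The within-section statistic
is the mean rather than the peak for noise robustness (the peak is
available via `stat="peak"`). The clipping keeps small residuals where a
druse is not present as small non-negative values, so downstream ratios
stay interpretable. Known bias: when a druse is wide along the B-scan
axis its tail leaks into the flanking sections, inflating the baseline
by up to ~2 μm at the default geometry and correspondingly shrinking
measured heights; this reproduces how the flanking protocol behaves on
real scans and stays within the ≤3 μm median-error budget the tests
enforce.

## Longitudinal tracking and change statistics

Visible detections are linked across consecutive visits by greedy
nearest-centroid matching within a physical radius (default 200 μm,
about two B-scan pitches); unmatched detections start new tracks, and
distance ties are broken toward the earlier track and logged. Only
visible detections seed tracks — isolated supra-threshold noise spikes
fail the visibility criterion and would otherwise flood the track list —
but every track is then re-measured at its anchor footprint in *every*
visit's thickness map (flanking baseline subtracted, clipped at 0), so
every location that ever carried a druse contributes a height at every
timepoint, including 0 before appearance and after disappearance.
Merging and splitting of drusen between visits is not modelled; the
linkage stays 1:1.

Three per-arm summaries (arms pool both eyes; `eye_id` is retained for
stratified re-analysis):

* **Count series** — tracks visible at the visit.
* **Mean height change** — mean height over all tracked locations at the
  visit minus the same mean at baseline; positive = growth. Drusen are
  pooled directly across eyes rather than averaged per eye first, so
  each druse is one observation, matching the ratio analysis.
* **Change ratios** — `h(t)/h(0)` per track with two exact degenerate
  rules: a zero baseline sets the denominator to 1 (the ratio is then
  numerically the later height in μm, a deliberate unit mix that keeps
  appearing drusen in the plot), and a zero later height gives ratio 0.
  Ratios are classified into >1, =1, <1 and =0 buckets; the =1 bucket
  uses a ±0.05 tolerance, a reporting choice with no effect on the
  underlying values.

The reference count series for the treated (injected, OS) eyes of the
two-macaque study — 25, 21, 23, 25, 32 drusen at 0/3/6/9/12 months — is
packaged as `INJECTED_EYE_DRUSEN_COUNTS`; only the endpoints of the
untreated series are published, so its intermediate visits are not
encoded (the 9-month value 41 follows from the published 9→12 increment
of seven).

## POS clearance

Dots are retained when diameter > 2 μm, strictly: a dot of exactly 2 μm
is excluded. Ten axis-aligned square fields of 40,000 μm² (side 200 μm)
are placed with centers uniform in the 1.5 mm-radius sampling disk,
non-overlapping by rejection sampling (the overlap rule is a design
choice; the protocol only says "selected randomly"), deterministic under
a fixed seed. Cells belong to a field when their centroid lies inside
it and dots by their center point, avoiding double counting; cells
straddling field borders are therefore counted in exactly one field,
never fractionally. Dots-per-cell is averaged over the ten fields per
mount, and the clearance statistic is 100 × (11 am mean)/(8 am mean).
Fields are drawn independently for the two clock times, as the two
times come from different mounts in the real protocol. A zero 8 am mean
raises an undefined-ratio error rather than returning infinity.

## Reporting statistics

* **Lipid composition**: per-sample percent-of-sum by class (sums to 100
  by construction) and per-class species percentages; group means ± SEM.
  An all-zero sample is an error naming the sample.
* **Margin of error** on a phenotype frequency k/n: Wald half-width
  `z·√(p̂(1−p̂)/n)` at 95% by default. Wald is the convention assumed
  because none was stated with the published error bars; it degenerates
  to 0 at p̂ ∈ {0, 1}, so the Wilson half-width is available via
  `method="wilson"`.
* **Group tests**: two groups → Welch (unequal-variance) two-tailed t
  test — chosen over Student's t because equal variances were never
  asserted; more groups → one-way ANOVA. SEM = sd/√n per group; stars at
  0.05/0.01/0.001/0.0001. No multiple-testing correction is applied by
  default, matching the reporting convention of the study this package
  mirrors.

## Synthetic generators

The generators define the conditions under which the pipeline is
validated; all are deterministic given their spec (which embeds the
seed), to byte-identical tables.

**OCT volumes.** Both boundaries share a smooth sinusoidal undulation
(amplitude 5 μm, wavelength 2.5 mm) plus independent i.i.d. Gaussian
axial noise per boundary sample (sd 2 μm each, so thickness noise has sd
≈2.8 μm); the RPE/POS boundary additionally rises toward the vitreous by
one anisotropic Gaussian bump per active druse (σ 150 μm across B-scans
× 100 μm along them, within the 60–500 μm diameter range of real small
to intermediate drusen), with per-visit peak amplitudes encoding
appearance, growth, shrinkage and disappearance. The drusen-free
BrM-to-RPE/POS thickness is 30 μm. The analytic bump makes every
ground-truth height evaluable in closed form; at zero noise the
generator's peak equals the grid maximum up to the half-pixel
discretisation bound `A·[1 − exp(−(Δ/σ)²/2)]`. Not emulated: speckle,
segmentation failures, eye-motion artifacts, registration error between
visits (visits are index-aligned), and drusen with non-Gaussian
profiles — so passing tests demonstrate correctness of the measurement
rules, not robustness to segmentation quality.

**Flat mounts.** RPE cells are a centroidal (one Lloyd iteration)
Voronoi tessellation of a 1.7 mm-radius disk at 400 μm² mean cell area
(~23k cells); dots are per-cell Poisson (10/cell at 8 am; the 11 am set
is an independent redraw at rate × clearance fraction) placed uniformly
inside their cell, with diameters Normal(3, 1) μm truncated at 0.2 μm so
a known ~16% of dots falls at or below the 2 μm counting threshold. The
fixture catalog pins clearance fractions 0.40 ("rescued") and 0.80
("diseased"), the two published genotype percentages the recovery tests
target. Not emulated: spatial clustering of shed outer segments,
cell-size gradients with eccentricity, imaging vignetting.

**Lipid panels.** Species responses follow baseline class fractions
(retina-like: PC 0.45, PE 0.35, PS 0.08, PI 0.07, PG 0.03, BMP 0.02)
times per-(group, class) multiplicative effects, split evenly across 5
species per class, with log-normal noise at CV 0.15 and 6 samples per
group (the published panel size). Expected class percentages under an
effect are the closed-form renormalisation `f_c·s_c / Σ f·s`, which the
tests verify exactly at zero noise.

## Problem sizes and runtimes

The validation suites run at the study's native geometry: 61×512-point
volumes, two eyes per arm, five visits, 20 drusen per arm with
amplitudes 15–60 μm for recovery and effect-direction checks (10 seeded
replicates); full-size flat-mount pairs (five seeds per condition) for
clearance recovery; 2,000 simulations for the null calibration of the
two-group test. The complete suite runs in about two minutes on one
core.

## Known limitations

* Threshold-based counting under noise can occasionally split one druse
  into two visible components or promote a noise cluster, so noisy-study
  counts can differ from ground truth by ±1–2; exact count recovery
  holds at zero noise, and height/ratio statistics are insensitive to
  these rare extras because they carry near-zero heights.
* The flanking baseline inherits the protocol's bias for drusen wide
  along the B-scan axis (see above).
* The two-animal, two-arm design the longitudinal module mirrors does
  not support formal inference; the module reports descriptive
  statistics (counts, means, SEM) only.
* Whether flanking sections must be free of *all* drusen (not just the
  measured one) is unspecified in the source protocol; this
  implementation requires freedom from the measured druse only, which
  can bias baselines when two drusen sit within a few B-scans of each
  other.
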