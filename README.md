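# retquant

Quantification pipelines for two readouts of retinal-pigmented-epithelium
(RPE) health, plus the descriptive statistics that go with them:

1. **Longitudinal drusen morphometry on OCT.** Drusen — lipoprotein-rich
   deposits between the RPE and Bruch's membrane (BrM), the hallmark of
   early age-related macular degeneration — are measured from segmented
   OCT boundary surfaces as elevations of the RPE/photoreceptor-outer-
   segment (RPE/POS) boundary, tracked across visits, and summarised as
   count series, average height changes, and per-druse change ratios.
2. **Photoreceptor-outer-segment (POS) clearance on RPE flat mounts.**
   The RPE phagocytoses the outer-segment tips photoreceptors shed at
   light onset; clearance competence is read out as rhodopsin-positive
   dots per RPE cell at 11 am relative to 8 am.
3. **Reporting statistics**: percent-of-sum phospholipid class
   composition, binomial margins of error for phenotype frequencies, and
   Welch-t / one-way-ANOVA group comparisons with SEM.

Raw-image segmentation (OCT layer segmentation, flat-mount spot
detection) is upstream of this package: it consumes boundary tables and
dot/cell records. Seeded synthetic generators emulate all three input
kinds with analytically known ground truth, so every stage is testable
without any imaging data.

## The statistics being computed

For an eye scanned with 61 B-scans spaced 109 μm apart, **thickness** at
a grid point is the distance between the Choroid/BrM boundary and the
RPE/POS boundary, `T(b, a) = z_BrM − z_RPE/POS` (μm). Druse footprints
are 4-connected components of the excess of `T` over a per-B-scan
running-median reference. A druse's height in section `b` is the mean
thickness over its footprint minus the **flanking baseline** — the
thickness averaged over the first drusen-free section before the
footprint and the first after it — clipped at 0, and its **average
height** `h` is the mean over every section in which it appears.

Per druse and visit `t`, the **change ratio** is

```
r(t) = h(t) / h(0),   with  h(0) = 0  ⇒  denominator set to 1,
                      and   h(t) = 0  ⇒  r = 0
```

so a druse that appeared during the study contributes its height
numerically, and a disappeared druse contributes 0. Growth means
`r > 1`. The per-arm **mean height change** at `t` is
`mean_tracks h(t) − mean_tracks h(0)` (positive = growth), over every
tracked location whether or not a druse is present there at `t`.

For flat mounts, dots with diameter **strictly greater than 2 μm** are
counted in ten randomly placed square fields of 40,000 μm² within
1.5 mm of the mount center; dots-per-cell is averaged over fields, and
**percent remaining** = `100 × (mean dots/cell at 11 am) / (mean
dots/cell at 8 am)`.

Lipid species responses are normalised per sample:
`class% = 100 × Σ_class response / Σ_all response` (summing to 100), and
per class, `species% = 100 × response / Σ_class response`.

## Worked example

Simulate a two-arm longitudinal study (two animals; left eyes treated so
drusen shrink 15% per 3 months, right eyes untreated and growing 15%),
then run the full chain — thickness, detection, flanking-baseline
heights, tracking, summaries:

```python
from retquant import synthetic as syn, morphometry as mm, longitudinal as lng

boundaries, truth = syn.generate_two_arm_study(
    syn.OctStudySpec(), n_drusen_per_arm=20,
    growth_multipliers={"injected": 0.85, "uninjected": 1.15}, seed=3)
volumes = [mm.BoundaryVolume.from_dataframe(sub)
           for _, sub in boundaries.groupby(["eye_id", "timepoint_months"])]
tracks = lng.track_study(volumes)
print(lng.summarize(tracks)[["arm", "timepoint_months", "n_drusen",
                             "mean_height_change_um", "mean_ratio", "sem_ratio"]]
      .round(3).to_string(index=False))
```

```
       arm  timepoint_months  n_drusen  mean_height_change_um  mean_ratio  sem_ratio
  injected               0.0        20                  0.000       1.000      0.000
  injected               3.0        20                 -1.225       0.915      0.015
  injected               6.0        20                 -2.560       0.817      0.015
  injected               9.0        19                 -3.535       0.741      0.024
  injected              12.0        19                 -4.322       0.689      0.023
uninjected               0.0        20                  0.000       1.000      0.000
uninjected               3.0        20                  1.333       1.101      0.015
uninjected               6.0        20                  2.376       1.185      0.020
uninjected               9.0        20                  4.380       1.332      0.027
uninjected              12.0        20                  5.876       1.440      0.026
```

All 20 seeded drusen per arm are recovered at baseline; the treated arm
shows negative mean height change and mean ratios below 1 (shrinkage),
the untreated arm the opposite — the orderings the longitudinal analyses
are designed to expose. Two drusen in the treated arm shrink below the
visibility criterion by 9 months, so its count drops to 19.

POS clearance, with ground-truth clearance fraction 0.4:

```python
from retquant import clearance as clr
mount = syn.generate_flatmount(syn.FlatMountSpec(clearance_fraction_11am=0.4, rng_seed=0))
res = clr.clearance_percent(mount.cells, mount.dots, seed=0, mount_pair_id="demo")
print(f"dots/cell 8am={res.mean_dots_per_cell_8am:.2f}  11am={res.mean_dots_per_cell_11am:.2f}  "
      f"percent remaining={res.percent_remaining:.1f}%")
```

```
dots/cell 8am=8.20  11am=3.36  percent remaining=40.9%
```

The pipeline recovers the simulated 40% clearance within sampling error.

A `retquant` command-line tool exposes the same stages
(`simulate-oct`, `simulate-flatmount`, `simulate-lipids`, `measure`,
`track`, `summarize`, `clearance`, `lipids`, `report`).

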