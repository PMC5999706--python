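# taupet

Dual-tracer preclinical tau PET quantification and 3D immunofluorescence
tau-load analysis, with seeded synthetic phantoms.

`taupet` is a reusable, tested implementation of the analysis chain used in
head-to-head small-animal tau-tracer comparison studies: transgenic mice with
brainstem tau pathology (P301S) versus wild-type controls, imaged
longitudinally with two tau radioligands (an arylquinoline with fast brain
washout, THK5117-like, and a pyridoindole with strong bone uptake,
T807-like), validated *ex vivo* by volumetric confocal microscopy of
tau-stained tissue. Because studies of this kind rest on animal data that
cannot ship with code, the package includes first-class synthetic generators
with known ground truth, so the entire chain runs, validates and reproduces
its behaviour from a single seed.

## What it computes

**Dynamic PET quantification** (`taupet.petquant`). For an atlas-registered
4D image with frame schedule: VOI time-activity curves (TACs); windowed
duration-weighted mean images; target/reference ratio curves; the
ratio-stability onset (earliest time from which the least-squares slope of
the ratio curve satisfies |slope| ≤ tol·mean); and the standardized uptake
value ratio

    SUVR_target/ref(w) = mean activity in target over window w
                         ─────────────────────────────────────
                         mean activity in reference over w

with tracer defaults brainstem/striatum+septum over 40–60 min and
brainstem/cerebellum over 30–60 min. Washout is summarized as the percent of
peak activity remaining at given times; extracerebral uptake as
region/whole-brain ratios.

**Group statistics** (`taupet.groupstats`). Percent difference
100·(μ_TG − μ_WT)/μ_WT, Cohen's *d* with the pooled SD, pooled-variance
Student *t*-tests (two-sample, paired, and from printed summary statistics;
Welch behind a flag), longitudinal percent change on matched animals, and
Pearson correlation for PET–histology validation.

**Voxel-wise maps** (`taupet.voxelmaps`). Reference-scaled SUVR images,
per-voxel two-sample or paired *t*-maps inside a brain mask, one-sided
suprathreshold masks (t ≥ 2 for group contrasts, t ≥ 1 for longitudinal
maps, uncorrected), and the dice coefficient 2|A∩B|/(|A|+|B|) between
binary maps.

**3D tau burden** (`taupet.ihc`). For 16-bit confocal stacks with
anisotropic voxels (0.35 × 0.35 × 1.0 µm): local background subtraction,
an 80th-percentile minimum-intensity threshold, removal of connected
patches smaller than 1 µm, detection of tau-positive somata (components
≥ 3 µm in every direction), and %tau per volume.

**Synthetic data** (`taupet.synthetic`). A mouse-head phantom whose six VOIs
match the study's volumes (brainstem 11, striatum+septum 38, cerebellum 56,
whole brain 525, petrous bone 9, Harderian glands 40 mm³), bi-exponential
regional kinetics calibrated so whole-brain washout retains 57%/11%
(THK5117-like) or 72%/26% (T807-like) of peak at 10/60 min, PSF blur
producing extracerebral spill-in, seeded cohorts with genotype effects and
log-normal between-animal variability — and confocal-like stacks containing
ellipsoidal somata, sub-micrometre speckles, structured background, and
Poisson + read noise, with exact ground-truth masks.

**Study orchestration** (`taupet.study`, CLI `taupet run-study`): the whole
design end to end — two tracers × two sessions × (7 TG + 7 WT), dropout
handling, a result-overview table, longitudinal and voxel-wise analyses,
dice between tracers, and a PET–histology correlation — deterministic per
seed, with provenance in every report.

## Worked example

```python
from taupet import (
    PhantomSpec, CohortSpec, build_atlas, generate_cohort,
    compute_suvr, suvr_group_table,
)

phantom = PhantomSpec.default("t807")          # 0.25 mm grid, 0-65 min frames
atlas = build_atlas()
cohort = CohortSpec(n_tg=7, n_wt=7, brainstem_effect_frac=0.17,
                    between_animal_cv=0.05, tracer="t807", seed=42)
records = [
    compute_suvr(scan.image, atlas, "brainstem", "striatum_septum",
                 (40, 60), scan.animal_id, scan.genotype, "t807")
    for scan in generate_cohort(cohort, phantom)
]
table = suvr_group_table(records)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

```
tracer  mean_tg  sd_tg  n_tg  mean_wt  sd_wt  n_wt  percent_diff  percent_diff_rounded  cohens_d    t  df        p
  t807     1.27 0.0622     7     1.07 0.0423     7          18.8                    19      3.79 7.08  12 1.28e-05
```

The transgenic group's brainstem-to-striatum SUVR comes out ~19% above
wild-type (the configured 17% generator effect, shifted by partial-volume
attenuation from the phantom's 0.2 mm PSF and this cohort's sampling
noise), with Cohen's *d* ≈ 3.8 and *p* ≈ 1e-5 by the pooled two-sample
*t*-test — the same analysis applied to a real cohort's SUVR table.

The full phantom study is one command:

```bash
taupet run-study --seed 1 --out results/study
```

which writes `suvr.csv` (per animal × tracer × session), `table1.csv`
(the result-overview table), `report.json` (longitudinal changes, dice
between the tracers' t ≥ 2 maps, PET–IHC correlation, provenance) and the
t-maps as NIfTI.

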