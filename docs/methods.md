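# Methods

This note documents the models behind `taupet`, the parameters that matter,
what the synthetic generators do and do not emulate, the numerical
conventions, and the design choices made where several reasonable options
existed. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted that the code does not
itself check.

## Dynamic PET model and quantification

**Containers.** A `DynamicImage` is a 4D activity-concentration array
(arbitrary units) with an explicit frame schedule in minutes post-injection
(p.i.); frames are strictly increasing and non-overlapping. A `LabelAtlas`
is an integer label volume on the same grid with a name map and optional
composite VOIs (`whole_brain` is the union of the four brain labels).
Images are assumed atlas-registered; no registration or motion correction
is implemented — upstream tooling performs those, and this package starts
where they end.

**Frame aggregation.** Windowed images and SUVR both use the
duration-weighted *mean* over frames, with partial frames weighted by their
temporal overlap with the window. Any consistent choice (mean vs sum)
cancels in a ratio; the mean keeps static images in concentration units and
makes the result independent of how finely the schedule subdivides a
window. VOI means are plain voxel-count means (whether the upstream
software uses intensity weighting is unknown; unweighted is assumed).

**SUVR.** `compute_suvr` evaluates the windowed duration-weighted mean of
the target and reference VOIs and returns their ratio. By linearity this
equals the ratio of the `sum_frames` VOI means, a contract the tests assert
exactly. Tracer defaults: brainstem/striatum+septum over 40–60 min for the
T807-like profile, brainstem/cerebellum over 30–60 min for the
THK5117-like profile. Reference regions are configuration, not code, so
alternative (e.g. swapped or modified) reference analyses are a config
change.

**Ratio stability.** The usable SUVR window is found by scanning candidate
onsets (frame midpoints, earliest first) and accepting the first for which
the least-squares line through the remaining ratio points has
|slope| ≤ `slope_tol` × (mean ratio), with at least three points and a
minimum span. Defaults `slope_tol = 0.002/min`, `min_span = 20 min`. The
quantitative criterion is this package's own (the underlying idea — a
flat late segment of the ratio TAC — admits many formalizations); the
brute-force scan over all onsets is the test oracle, and on the default
phantoms both tracer profiles stabilize at or before 30 min p.i.

**Washout and relative uptake.** `washout_metrics` reports the percent of
peak remaining at requested times (linear interpolation between frame
midpoints; the peak is the maximum frame value — with the default schedule
a midpoint falls exactly on the modelled peak time).
`relative_uptake` reports region/whole-brain at the frame covering a
requested time.

## Synthetic PET phantom

**Geometry.** Six structures are defined analytically in millimetres
(ellipsoids; bilateral pairs for petrous bone and Harderian glands) and
voxelized onto a default 64×80×64 grid at 0.25 mm — a desk-scale grid, not
scanner-native resolution. Voxelized volumes land within ~1% of the target
VOI volumes (11 / 38 / 56 / 525 / 9 / 40 mm³), except the petrous bone
(−11%, clipped where it abuts the brain ellipsoid; the tests enforce a 20%
band). The brainstem is painted last so its volume is exact where
neighbouring structures approach.

**Kinetics.** The study's source data constrain only two points of each
tracer's whole-brain washout (fraction of peak at 10 and 60 min p.i.), so
the phantom uses the simplest curve with those degrees of freedom: a
linear ramp to a peak at 2.5 min followed by a bi-exponential tail,

    C(t) = C_peak · [ f·e^(−k_f (t−t_p)) + (1−f)·e^(−k_s (t−t_p)) ],

with (k_f, k_s) solved exactly (nested bisection) so the fraction of peak
hits the targets: 57%/11% at 10/60 min for the fast THK5117-like profile
and 72%/26% for the slower T807-like profile. Brain regions share the
calibrated rates; the fast/slow split differs slightly per region
(brainstem 0.50, cerebellum 0.60, others 0.55) so target/reference ratio
curves drift early and flatten late, giving the stability analysis
something to find. Extracerebral structures get their own curves: a
persistent high-uptake bone curve for the T807-like profile
(defluorination-like) and a high, slowly clearing Harderian-gland curve
for the THK5117-like profile. The published extracerebral percentages are
real-tissue values and are *not* calibration targets; only the qualitative
ordering (more bone signal for T807-like, more gland signal for
THK5117-like) is reproduced.

**Resolution and noise.** Each region's indicator field is blurred once
with an isotropic Gaussian PSF (default σ = 0.2 mm — a deliberately mild,
sub-voxel-scale blur appropriate to the shrunken desk-scale geometry); a
frame is then a linear combination of these static fields, which makes
cohort generation cheap and keeps the image model exactly linear in
regional activity. Noise is Gaussian with SD proportional to local
activity (`noise_sd_frac`, default 5%), drawn per voxel per frame.
Rendering is float64 so that with blur and noise off, every voxel's TAC
equals its region's analytic curve to machine precision — the basis of the
exact-recovery tests.

**Cohorts.** Transgenic animals have their brainstem curve scaled by
(1 + effect). Between-animal variability is a mean-one log-normal factor
drawn independently per animal *and region* (σ² = ln(1+CV²), default CV
5%); per-animal, per-region factors are what give SUVR a realistic group
SD (≈ √2·CV, matching the published 4–9%), since a single global factor
would cancel in every ratio. Factors are drawn from the cohort seed only,
so the same animals (same biology) recur across imaging sessions and
tracers, while the noise realization is re-seeded per (session, animal).
Spill-in is emulated physically: the hot bone/gland structures blur into
adjacent brain, and a shell-VOI test asserts that measured spill-in grows
monotonically with the PSF width.

**Effect calibration in the study config.** The PSF partial-volume effect
attenuates a configured brainstem elevation by a fixed factor (≈ 0.83 on
the 11 mm³ brainstem at σ = 0.2 mm). The default study configuration
therefore calibrates its generator effects so that the *measured* group
differences land on the reported-contrast targets (+14%/+23% for the T807-like
arm, +5%/+10% for the THK5117-like arm), inverting the attenuation with a
single noise-free probe cohort. Monte-Carlo recovery is checked against
the noise-free pipeline value (the oracle that isolates noise and
between-animal variability, which contribute no material bias) and against
the configured effect.

## Group statistics

Percent difference is 100·(μ_TG − μ_WT)/μ_WT (integer-rounded for display,
full precision retained). Cohen's *d* uses the pooled SD; the unpaired
test is the pooled-variance Student *t* (Welch behind a flag), two-tailed
throughout, α = 0.05, no multiplicity correction — matching the study
design being emulated. Degenerate inputs follow explicit conventions:
zero pooled SD with equal means gives t = 0, p = 1; paired vectors with
constant non-zero differences are an error (infinite t is not a useful
number). Published effect sizes for these contrasts cannot be regenerated
exactly from the rounded printed summaries (pooled *d* from the baseline
summaries gives 1.74 where 1.64 was printed — presumably computed on
unrounded per-animal data), so printed *d* values are not used as test
oracles; the printed significance *bounds* (p < 0.01, p < 0.001), which
are robust to rounding, are.

## Voxel-wise maps

Static windowed images are divided by their reference-VOI mean
(idempotent by construction), stacked, and tested per voxel: pooled
two-sample *t* (df = n₁+n₂−2) or paired *t* (df = n−1) inside a brain
mask, with extracerebral voxels excluded. Thresholding is one-sided in
the TG > WT direction (t ≥ 2 for group maps ≈ p < 0.01 uncorrected at
these df; t ≥ 1 for longitudinal maps); no smoothing by default (an
optional Gaussian stage exists), no cluster-extent or multiplicity
correction. Dice is 2|A∩B|/(|A|+|B|), 0 when both maps are empty.

Two properties of small-sample voxel-wise maps matter for interpretation:

* Under any null noise, ~3% of brain voxels exceed t = 2 by chance
  (df ≈ 12), which at a 33,000-voxel brain is comparable to the 700-voxel
  brainstem itself. Localization is therefore asserted on the *main
  suprathreshold cluster* (largest 26-connected component), which on
  blur-free phantoms lies ≥ 95% inside the brainstem label.
* Region-coherent between-animal variability (the log-normal region
  factors) acts as a perfectly spatially correlated random effect: an
  unlucky draw can push an entire region's ratio past threshold at n = 7.
  Real small-cohort SPMs share this instability. The dual-tracer dice
  experiment therefore runs with biological CV off, isolating the spatial
  concordance of the two measurement chains (tracer-specific kinetics,
  windows and reference regions, common brainstem effect); it yields
  dice ≈ 0.66 at t ≥ 2. The end-to-end study keeps CV at its realistic
  value and simply reports whatever dice results.

## 3D immunofluorescence tau load

Stacks are (z, y, x) arrays with anisotropic physical voxels
(default 1.0 µm axial, 0.35 µm lateral). The chain:

1. **Local background subtraction.** Each z-slice's background is
   estimated on a grid of `block_um` (default 20 µm) tiles as a robust
   low percentile (default 25th) of tile intensities, bilinearly
   interpolated to full resolution, subtracted, clipped at zero. A
   percentile this low ignores bright structures occupying up to 75% of a
   tile; a plain tile *median* is dragged upward wherever a large soma
   covers half a tile and then carves holes into it on subtraction (this
   failure mode was observed directly and motivated the estimator). The
   estimator resolves background variation with wavelength longer than
   the block; faster background structure passes through — a stated
   limitation.
2. **Percentile threshold.** Voxels ≥ the 80th percentile of the
   corrected stack (inclusive, ties in; a degenerate constant stack is
   flagged in provenance).
3. **Sub-micrometre patch removal.** 26-connected components are removed
   when they are smaller than 1 µm *either* by bounding-box extent
   (≤ 1 µm along all three axes — ties removed) *or* by total volume
   (< 1 µm³). The volume clause matters with anisotropic voxels: two
   diagonally-touching voxels span two 1 µm slices by bounding box while
   containing 0.25 µm³ of substance; counting such pairs as ≥ 1 µm
   structure would let the upper tail of background noise survive almost
   entirely (nearly every above-threshold noise voxel has a 26-neighbour
   in an adjacent slice) and would pin measured %tau near the threshold
   complement regardless of true burden.
4. **Soma detection.** Components with bounding-box extent ≥ 3 µm along
   *every* axis are tau-positive somata. Axis-aligned extent (not Feret
   diameter) is used: deterministic, cheap, and a literal reading of
   "in all spatial directions". Sub-criterion components remain in the
   tau mask but are not somata.
5. **Tau volume load.** 100 × (tau ∩ ROI)/|ROI| with the soma count
   attached.

**Dynamic range of the fixed-percentile design.** A fixed 80th-percentile
threshold selects ~20% of voxels by construction. When the true tau
fraction is at or above 20%, the threshold falls inside the soma intensity
distribution, background is excluded entirely, and the measurement
saturates at 20%. Somewhat below 20%, the mask contains the brightest
background tail, whose surviving fraction after the patch filter grows
with its density; below ~13% that tail becomes dense enough to form
percolating 26-connected clusters that no size filter can remove, and the
measurement is dominated by background. The method's usable range is
therefore heavy burden near the threshold complement (~16.5–20.5% at
q = 80), which is the regime of the brainstem pathology being emulated;
the burden-gradient experiment spans exactly this range and recovers the
truth with R ≈ 0.99. This is a real limitation of percentile thresholding,
stated rather than hidden.

## Synthetic confocal stacks

Default stacks are 256×256×30 voxels at the true acquisition's voxel size
(0.35/0.35/1.0 µm) — a scaled-down field of view, not a rescaled one, so
micrometre-based filters are exercised faithfully. Somata are ellipsoids
with per-axis diameters uniform in 6–10 µm, placed sequentially
largest-first with a clearance pad of at least one voxel per axis; the pad
is a true morphological dilation of the voxelized soma (an analytically
enlarged ellipsoid does not contain the diagonal neighbours of equatorial
voxels and can allow two somata to touch). When rejection sampling stalls
near jamming, an exact FFT-convolution search finds a remaining free
centre if one exists. `n_somata` caps a placement pool; by default
placement stops when somata occupy 20.5% of the stack
(`target_fill_fraction`), the heavy-burden operating point of the
segmentation chain, and the ground-truth count is the number actually
placed. Speckles are 1–2-voxel artefacts (sub-micrometre extent on every
axis), kept clear of somata. Intensities: a multiplicative low-frequency
background field (±5%, wavelength ≫ the subtraction block) over a 1500-count
base, somata at +15,000 counts, speckles dim (25% of soma contrast,
sub-resolution partial-volume), Poisson photon noise plus Gaussian read
noise (SD 50), clipped to 16 bits. The generator does **not** emulate:
neurites and threads, depth-dependent attenuation, optical PSF blur and
axial elongation, chromatic or stage drift, or tissue autofluorescence
texture — so passing recovery tests demonstrate correctness of the
segmentation logic and its physical-size criteria, not robustness to every
real acquisition artefact.

Recovery at the default operating point is exact by construction and
verified over ≥ 20 seeds: detected soma count equals the placed count, no
speckle voxel survives the cleaned mask, and measured %tau is within
2 points of truth (the residual bias is the trimmed dim tail of the soma
intensity distribution).

## End-to-end study

`run_study` simulates two tracer arms × two sessions over one cohort
(7 TG + 7 WT by default), applies per-arm SUVR quantification, builds the
result-overview table (means ± SD, n, Δ%, Cohen's d, pooled t, p),
longitudinal percent change with paired tests on complete pairs only
(animals dropped from an arm/session — by default two TG animals missing
the THK5117-like follow-up — are excluded pairwise but kept in unpaired
cells), voxel-wise group maps at follow-up with dice between the tracers'
t ≥ 2 masks, paired longitudinal maps at t ≥ 1, and a PET–histology arm:
the TG animals that completed every arm contribute one synthetic stack
each, whose true burden follows the same latent brainstem factor that
scales their PET kinetics (base fraction 19%, linear link, clipped to the
segmentation's resolved range), and measured %tau is correlated with each
tracer's follow-up SUVR. Reports embed the package version, seed, and a
SHA-256 of the configuration; every table number is recomputable from the
per-animal CSV the run writes.

## Problem sizes and determinism

Default experiment sizes: 64×80×64 phantom grid (21 frames), cohorts of
7 + 7, 20 Monte-Carlo seeds for recovery experiments, 20 seeds for
confocal recovery, 10-stack burden gradients, 1000 replicates for type-I
error. These sizes make every distributional claim checkable in minutes
while keeping Monte-Carlo standard errors well inside the asserted
tolerances. All generators take explicit integer seeds and are
bit-reproducible; derived seeds use `numpy` `SeedSequence` spawning so no
two experiments share a stream.

## Known limitations

* No scanner physics (attenuation, scatter, randoms, reconstruction), no
  motion, no registration error; inputs are assumed registered.
* No kinetic modelling (compartment fits, DVR/BP_ND), no partial-volume
  correction, no blood/metabolite correction — SUVR only, as in the
  emulated design.
* The voxel-wise module is a minimal t-map implementation, not an SPM
  feature set (no GLM design matrices, no random-field p-values).
* The percentile-threshold segmentation resolves burden only near the
  threshold complement (see above); quantifying sparse pathology would
  require an absolute or histogram-derived threshold instead.
* Region-constant biological variability makes n = 7 voxel-wise maps
  regionally unstable by construction; study-level dice is reported, not
  asserted.
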