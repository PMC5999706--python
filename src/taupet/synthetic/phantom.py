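"""Seeded dynamic-PET phantom and cohort generator.

The phantom emulates the structure of a dual-tracer mouse tau-imaging
study on a desk-scale grid: a mouse-head-like geometry with six VOIs
(brainstem, striatum+septum, cerebellum, rest of brain, petrous bone,
Harderian glands) whose physical volumes approximate the study atlas
(11, 38, 56, 525 total brain, 9 and 40 mm^3), per-region uptake-washout
kinetics, optional point-spread-function blur that produces spill-in
from hot extracerebral structures, and multiplicative Gaussian noise.

Two built-in tracer profiles encode the observed washout behaviour:

* ``thk5117`` — fast washout; whole-brain activity retains 57% of peak
  at 10 min and 11% at 60 min; high Harderian-gland uptake.
* ``t807`` — slower washout (72% / 26% of peak at 10 / 60 min); strong,
  persistent petrous-bone uptake (defluorination-like).

Cohorts add a transgenic (TG) brainstem elevation and log-normal
between-animal variability; everything is bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ..images import DynamicImage, LabelAtlas
from .kinetics import KineticParams

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "AnimalScan",
    "tracer_profile",
    "default_frame_schedule",
    "build_atlas",
    "generate_pet_phantom",
    "generate_cohort",
    "adjacent_shell_mask",
]

# ----------------------------------------------------------------- geometry
# Canonical geometry in mm, offsets relative to the grid centre.  Ellipsoid
# semi-axes are chosen so analytic volumes match the target VOI volumes;
# voxelization on the default 0.25 mm grid stays within a few percent.
BRAINSTEM, STRIATUM_SEPTUM, CEREBELLUM, BRAIN_REST, PETROUS_BONE, HARDERIAN = 1, 2, 3, 4, 5, 6

LABEL_NAMES: dict[int, str] = {
    BRAINSTEM: "brainstem",
    STRIATUM_SEPTUM: "striatum_septum",
    CEREBELLUM: "cerebellum",
    BRAIN_REST: "brain_rest",
    PETROUS_BONE: "petrous_bone",
    HARDERIAN: "harderian_glands",
}
VOI_GROUPS: dict[str, tuple[int, ...]] = {
    "whole_brain": (BRAINSTEM, STRIATUM_SEPTUM, CEREBELLUM, BRAIN_REST),
}

# (center_mm, semi_axes_mm) per structure; bilateral structures have two centres
_BRAIN = ((0.0, 0.0, 0.0), (4.0, 6.0, 5.222))
_ELLIPSOIDS: dict[int, list[tuple[tuple[float, float, float], tuple[float, float, float]]]] = {
    BRAINSTEM: [((0.0, 2.2, -2.2), (1.0, 2.5, 1.05))],
    STRIATUM_SEPTUM: [((0.0, -3.0, 0.5), (2.087, 2.087, 2.087))],
    CEREBELLUM: [((0.0, 4.0, 1.0), (3.0, 1.5, 2.97))],
    PETROUS_BONE: [
        ((-3.4, 2.2, -3.4), (1.024, 1.024, 1.024)),
        ((3.4, 2.2, -3.4), (1.024, 1.024, 1.024)),
    ],
    HARDERIAN: [
        ((-3.0, -5.8, -2.2), (1.684, 1.684, 1.684)),
        ((3.0, -5.8, -2.2), (1.684, 1.684, 1.684)),
    ],
}

# Reference VOI volumes (mm^3) the default atlas approximates.
REFERENCE_VOLUMES_MM3: dict[str, float] = {
    "brainstem": 11.0,
    "striatum_septum": 38.0,
    "cerebellum": 56.0,
    "whole_brain": 525.0,
    "petrous_bone": 9.0,
    "harderian_glands": 40.0,
}


def default_frame_schedule() -> tuple[tuple[float, float], ...]:
    """0-65 min dynamic schedule with short early frames (minutes)."""
    edges = [0, 0.5, 1, 1.5, 2, 3, 4, 5, 7.5, 10, 12.5, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60, 65]
    return tuple((float(a), float(b)) for a, b in zip(edges[:-1], edges[1:]))


def _ellipsoid_mask(shape, voxel_size_mm, center_mm, semi_mm) -> np.ndarray:
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel_size_mm)
    ]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij", sparse=True)
    cx, cy, cz = center_mm
    ax, ay, az = semi_mm
    return ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2 <= 1.0


def build_atlas(
    grid_shape: tuple[int, int, int] = (64, 80, 64),
    voxel_size_mm: tuple[float, float, float] = (0.25, 0.25, 0.25),
) -> LabelAtlas:
    """Voxelize the canonical geometry onto a grid."""
    labels = np.zeros(grid_shape, dtype=np.int16)
    labels[_ellipsoid_mask(grid_shape, voxel_size_mm, *_BRAIN)] = BRAIN_REST
    # interior structures overwrite brain tissue; brainstem painted last so
    # its volume is exact even where neighbouring structures come close
    for lab in (CEREBELLUM, STRIATUM_SEPTUM, BRAINSTEM):
        for center, semi in _ELLIPSOIDS[lab]:
            labels[_ellipsoid_mask(grid_shape, voxel_size_mm, center, semi)] = lab
    # extracerebral structures never overwrite brain voxels
    for lab in (PETROUS_BONE, HARDERIAN):
        for center, semi in _ELLIPSOIDS[lab]:
            m = _ellipsoid_mask(grid_shape, voxel_size_mm, center, semi)
            labels[m & (labels == 0)] = lab
    return LabelAtlas(labels, LABEL_NAMES, tuple(voxel_size_mm), VOI_GROUPS)


# ----------------------------------------------------------------- kinetics
def tracer_profile(name: str) -> dict[str, KineticParams]:
    """Per-region kinetic defaults for a named tracer profile.

    Brain regions share calibrated washout rates but differ slightly in the
    fast/slow split (the brainstem clears a little slower, the cerebellum a
    little faster), so target/reference ratio curves move early on and
    flatten late, as ratio-stability analysis expects.
    """
    if name == "thk5117":
        base = KineticParams.from_washout_targets(2.5, 1.0, ((10.0, 0.57), (60.0, 0.11)), 0.55)
        bone = KineticParams(10.0, 0.8, 0.5, 0.10, 0.02)
        glands = KineticParams(5.0, 3.0, 0.3, 0.05, 0.004)
    elif name == "t807":
        base = KineticParams.from_washout_targets(2.5, 1.0, ((10.0, 0.72), (60.0, 0.26)), 0.55)
        bone = KineticParams(10.0, 2.0, 0.05, 0.05, 0.001)
        glands = KineticParams(5.0, 1.5, 0.4, 0.05, 0.005)
    else:
        raise KeyError(f"unknown tracer profile {name!r}; available: 't807', 'thk5117'")
    return {
        "brainstem": replace(base, fast_fraction=0.50),
        "striatum_septum": base,
        "cerebellum": replace(base, fast_fraction=0.60),
        "brain_rest": base,
        "petrous_bone": bone,
        "harderian_glands": glands,
    }


# --------------------------------------------------------------------- spec
@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to generate one phantom acquisition."""

    regions: Mapping[str, KineticParams]
    grid_shape: tuple[int, int, int] = (64, 80, 64)
    voxel_size_mm: tuple[float, float, float] = (0.25, 0.25, 0.25)
    frame_schedule: tuple[tuple[float, float], ...] = field(default_factory=default_frame_schedule)
    psf_sigma_mm: float = 0.2
    noise_sd_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if len(self.frame_schedule) == 0:
            raise ValueError("frame schedule is empty")
        sched = np.asarray(self.frame_schedule, dtype=float)
        if np.any(sched[:, 1] <= sched[:, 0]) or (
            len(sched) > 1 and np.any(sched[1:, 0] < sched[:-1, 1])
        ):
            raise ValueError("frame schedule must be strictly increasing and non-overlapping")
        if self.psf_sigma_mm < 0:
            raise ValueError("psf_sigma_mm must be >= 0")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        unknown = set(self.regions) - set(LABEL_NAMES.values())
        if unknown:
            raise ValueError(f"unknown region names {sorted(unknown)}")

    @classmethod
    def default(cls, tracer: str = "t807", **overrides) -> "PhantomSpec":
        return cls(regions=tracer_profile(tracer), **overrides)

    @property
    def frame_start_min(self) -> np.ndarray:
        return np.asarray(self.frame_schedule, dtype=float)[:, 0]

    @property
    def frame_end_min(self) -> np.ndarray:
        return np.asarray(self.frame_schedule, dtype=float)[:, 1]

    @property
    def frame_mid_min(self) -> np.ndarray:
        return 0.5 * (self.frame_start_min + self.frame_end_min)


@dataclass(frozen=True)
class CohortSpec:
    """A TG vs WT cohort layered on top of a phantom."""

    n_tg: int
    n_wt: int
    brainstem_effect_frac: float = 0.14
    between_animal_cv: float = 0.05
    tracer: str = "t807"
    seed: int = 0

    def __post_init__(self):
        if self.n_tg < 1 or self.n_wt < 1:
            raise ValueError("n_tg and n_wt must be >= 1")
        if self.brainstem_effect_frac < 0:
            raise ValueError("brainstem_effect_frac must be >= 0")
        if self.between_animal_cv < 0:
            raise ValueError("between_animal_cv must be >= 0")


@dataclass(frozen=True)
class AnimalScan:
    animal_id: str
    genotype: str  # "TG" | "WT"
    image: DynamicImage
    region_factors: Mapping[str, float]


# ----------------------------------------------------------------- builders
def _region_basis(atlas: LabelAtlas, psf_sigma_mm: float) -> dict[int, np.ndarray]:
    """Per-label spatial basis: indicator, PSF-blurred if requested.

    The image model is linear in regional activity, so each frame is a
    weighted sum of these static fields — blur is applied once, not per
    frame, which keeps cohort generation cheap.
    """
    basis: dict[int, np.ndarray] = {}
    sigma_vox = [psf_sigma_mm / v for v in atlas.voxel_size_mm]
    for lab in LABEL_NAMES:
        ind = (atlas.labels == lab).astype(np.float32)
        if not ind.any():
            continue
        if psf_sigma_mm > 0:
            ind = ndimage.gaussian_filter(ind, sigma=sigma_vox)
        basis[lab] = ind
    return basis


def _activity_matrix(
    regions: Mapping[str, KineticParams],
    mids: np.ndarray,
    factors: Mapping[str, float] | None = None,
) -> dict[int, np.ndarray]:
    """label -> per-frame activity curve, with optional per-region factors."""
    name_to_label = {v: k for k, v in LABEL_NAMES.items()}
    out = {}
    for name, kin in regions.items():
        scale = 1.0 if factors is None else float(factors.get(name, 1.0))
        out[name_to_label[name]] = kin.curve(mids) * scale
    return out


def _render_dynamic(
    basis: Mapping[int, np.ndarray],
    activities: Mapping[int, np.ndarray],
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> DynamicImage:
    mids = spec.frame_mid_min
    shape = next(iter(basis.values())).shape
    # float64 accumulation: noise-free, blur-free phantoms must reproduce the
    # analytic regional curves to near machine precision
    data = np.zeros(shape + (mids.size,), dtype=np.float64)
    for lab, curve in activities.items():
        if lab in basis:
            data += basis[lab][..., None] * curve
    if spec.noise_sd_frac > 0:
        noise = rng.standard_normal(size=data.shape, dtype=np.float32)
        data = data + noise * (spec.noise_sd_frac * data)
    return DynamicImage(data, spec.frame_start_min, spec.frame_end_min, spec.voxel_size_mm)


def generate_pet_phantom(
    spec: PhantomSpec,
) -> tuple[DynamicImage, LabelAtlas, pd.DataFrame]:
    """Generate one phantom acquisition plus its analytic ground truth.

    Returns the dynamic image, the label atlas, and a tidy table of the
    noise-free regional curves (columns: region, frame_mid_min, activity).
    With ``psf_sigma_mm = 0`` and ``noise_sd_frac = 0`` every voxel's TAC
    equals its region's analytic curve exactly.
    """
    atlas = build_atlas(spec.grid_shape, spec.voxel_size_mm)
    basis = _region_basis(atlas, spec.psf_sigma_mm)
    activities = _activity_matrix(spec.regions, spec.frame_mid_min)
    rng = np.random.default_rng(spec.seed)
    img = _render_dynamic(basis, activities, spec, rng)
    rows = []
    for name, kin in spec.regions.items():
        for t, a in zip(spec.frame_mid_min, kin.curve(spec.frame_mid_min)):
            rows.append({"region": name, "frame_mid_min": float(t), "activity": float(a)})
    return img, atlas, pd.DataFrame(rows)


def _animal_factors(
    cohort: CohortSpec, region_names: Sequence[str]
) -> list[dict[str, float]]:
    """Mean-one log-normal per-animal, per-region multipliers.

    Drawn from the cohort seed only, so the same animals (same biology)
    recur across imaging sessions; session-specific noise is seeded
    separately in :func:`generate_cohort`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cohort.seed)]))
    n = cohort.n_tg + cohort.n_wt
    cv = cohort.between_animal_cv
    if cv == 0:
        return [{name: 1.0 for name in region_names} for _ in range(n)]
    sigma = float(np.sqrt(np.log1p(cv**2)))
    draws = rng.normal(loc=-0.5 * sigma**2, scale=sigma, size=(n, len(region_names)))
    return [
        {name: float(np.exp(draws[i, j])) for j, name in enumerate(region_names)}
        for i in range(n)
    ]


def generate_cohort(
    cohort: CohortSpec,
    phantom: PhantomSpec,
    session: int = 0,
    atlas: LabelAtlas | None = None,
    basis: Mapping[int, np.ndarray] | None = None,
) -> list[AnimalScan]:
    """Generate per-animal dynamic images for a TG vs WT cohort.

    TG animals have their brainstem kinetics scaled by
    ``1 + brainstem_effect_frac``.  ``session`` tags repeat imaging of the
    same animals: animal-level biology (the log-normal region factors) is
    identical across sessions, while the noise realization differs.
    """
    if atlas is None:
        atlas = build_atlas(phantom.grid_shape, phantom.voxel_size_mm)
    if basis is None:
        basis = _region_basis(atlas, phantom.psf_sigma_mm)
    region_names = list(phantom.regions)
    factors = _animal_factors(cohort, region_names)
    scans: list[AnimalScan] = []
    genotypes = ["TG"] * cohort.n_tg + ["WT"] * cohort.n_wt
    counters = {"TG": 0, "WT": 0}
    for idx, geno in enumerate(genotypes):
        counters[geno] += 1
        animal_id = f"{geno.lower()}{counters[geno]:02d}"
        regions = dict(phantom.regions)
        if geno == "TG" and "brainstem" in regions:
            regions["brainstem"] = regions["brainstem"].scaled(1.0 + cohort.brainstem_effect_frac)
        activities = _activity_matrix(regions, phantom.frame_mid_min, factors[idx])
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cohort.seed), int(session), idx])
        )
        img = _render_dynamic(basis, activities, phantom, rng)
        scans.append(AnimalScan(animal_id, geno, img, factors[idx]))
    return scans


def adjacent_shell_mask(
    atlas: LabelAtlas, voi: str, thickness_mm: float = 0.5, within: str | None = None
) -> np.ndarray:
    """Shell of voxels adjacent to a VOI (for spill-in measurements)."""
    n_iter = max(1, int(round(thickness_mm / min(atlas.voxel_size_mm))))
    core = atlas.mask(voi)
    shell = ndimage.binary_dilation(core, iterations=n_iter) & ~core
    if within is not None:
        shell &= atlas.mask(within)
    return shell
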