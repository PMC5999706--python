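"""Seeded confocal-like 3D stack generator with known tau ground truth.

Emulates 16-bit immunofluorescence stacks of tau-stained brainstem
tissue at 0.35 um lateral / 1.0 um axial sampling (array axes z, y, x):
bright ellipsoidal tau-positive somata (>= 3 um in every direction),
sub-micrometre speckle artefacts that must fail the 1 um patch
criterion, a low-frequency multiplicative background field, and
Poisson + Gaussian read noise.  The default stack is a 256 x 256 x 30
voxel analogue of a much larger acquisition; the physical voxel size is
preserved so micrometre-based filters are exercised faithfully.

Default soma sizes (6-10 um) and the default fill target (somata
occupying ~20.5% of the stack) emulate heavy neuronal tau pathology,
the regime the segmentation chain targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..ihc import MicroStack

__all__ = ["StackSpec", "IhcTruth", "generate_ihc_stack"]


@dataclass(frozen=True)
class StackSpec:
    """Parameters of one synthetic stack (sizes in um, axes z/y/x)."""

    stack_shape: tuple[int, int, int] = (30, 256, 256)
    voxel_size_um: tuple[float, float, float] = (1.0, 0.35, 0.35)
    n_somata: int = 230
    soma_diameter_um: tuple[float, float] = (6.0, 10.0)
    target_fill_fraction: float | None = 0.205
    n_speckles: int = 150
    background_level: float = 1500.0
    background_mod_frac: float = 0.05
    soma_intensity: float = 15000.0
    speckle_intensity_frac: float = 0.25
    read_noise_sd: float = 50.0
    min_gap_um: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.n_somata < 0 or self.n_speckles < 0:
            raise ValueError("object counts must be >= 0")
        lo, hi = self.soma_diameter_um
        if lo < 3.0:
            raise ValueError(
                "soma diameters below 3 um would contradict the ground-truth "
                "labelling (somata must pass the 3 um criterion on every axis)"
            )
        if hi < lo:
            raise ValueError("soma diameter range must be (lo, hi) with hi >= lo")
        if self.target_fill_fraction is not None and not 0.0 < self.target_fill_fraction < 0.5:
            raise ValueError("target_fill_fraction must be in (0, 0.5)")
        if self.n_speckles > 0 and max(self.voxel_size_um) > 1.0:
            raise ValueError(
                "speckles require voxel size <= 1 um on every axis to stay "
                "below the 1 um patch criterion"
            )
        for d, n, v in zip("zyx", self.stack_shape, self.voxel_size_um):
            if self.n_somata > 0 and n * v < hi + 2:
                raise ValueError(f"stack too small along {d} for the largest soma")


@dataclass(frozen=True)
class IhcTruth:
    """Ground truth accompanying a generated stack."""

    soma_mask: np.ndarray
    speckle_mask: np.ndarray
    n_somata: int
    tau_fraction: float  # (somata + speckles) voxels / stack voxels

    @property
    def tau_mask(self) -> np.ndarray:
        return self.soma_mask | self.speckle_mask


def _ellipsoid_local(semi_vox: np.ndarray) -> np.ndarray:
    """Boolean ellipsoid in a tight local box, given semi-axes in voxels."""
    ranges = [np.arange(-int(np.ceil(s)), int(np.ceil(s)) + 1) for s in semi_vox]
    zz, yy, xx = np.meshgrid(*ranges, indexing="ij", sparse=True)
    return (zz / semi_vox[0]) ** 2 + (yy / semi_vox[1]) ** 2 + (xx / semi_vox[2]) ** 2 <= 1.0


def _place(center: np.ndarray, local: np.ndarray, shape) -> tuple[tuple, np.ndarray] | None:
    """Slices into the full array for a local box centred at ``center``."""
    half = [(s - 1) // 2 for s in local.shape]
    starts = [c - h for c, h in zip(center, half)]
    stops = [s + e for s, e in zip(starts, local.shape)]
    if any(s < 0 for s in starts) or any(e > n for e, n in zip(stops, shape)):
        return None
    return tuple(slice(s, e) for s, e in zip(starts, stops)), local


def _free_center(
    occupancy: np.ndarray, enlarged: np.ndarray, margin: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """Uniformly sample a centre where the padded soma fits, or None.

    Exact: a centre is admissible iff the padded ellipsoid overlaps no
    occupied voxel, evaluated for all centres at once by convolution.
    """
    from scipy.signal import fftconvolve

    overlap = fftconvolve(occupancy.astype(np.float32), enlarged.astype(np.float32), mode="same")
    free = overlap < 0.5
    # enforce the fully-inside margin
    for ax, m in enumerate(margin):
        sl = [slice(None)] * 3
        sl[ax] = slice(0, int(m))
        free[tuple(sl)] = False
        sl[ax] = slice(occupancy.shape[ax] - int(m), None)
        free[tuple(sl)] = False
    idx = np.flatnonzero(free)
    if idx.size == 0:
        return None
    return np.array(np.unravel_index(int(rng.choice(idx)), occupancy.shape), dtype=int)


def generate_ihc_stack(spec: StackSpec) -> tuple[MicroStack, IhcTruth]:
    """Generate a stack and its ground truth; bit-identical per seed.

    Somata are ellipsoids with per-axis diameters drawn uniformly from
    ``soma_diameter_um`` (>= 3 um on every axis by construction) and are
    placed with at least ``min_gap_um`` clearance so they never touch;
    speckles are 1-2 voxel artefacts with sub-micrometre extent on every
    axis.  Raises ``RuntimeError`` if the requested density cannot be
    packed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.stack_shape)
    vox = np.asarray(spec.voxel_size_um, float)
    soma_mask = np.zeros(shape, dtype=bool)
    speckle_mask = np.zeros(shape, dtype=bool)
    occupancy = np.zeros(shape, dtype=bool)  # somata dilated by the gap

    lo, hi = spec.soma_diameter_um
    # draw all diameters up front and place the largest somata first --
    # sequential random packing reaches usefully higher densities that way.
    # n_somata is a pool cap; when target_fill_fraction is set, placement
    # stops as soon as the soma volume fraction reaches it.
    diams = rng.uniform(lo, hi, size=(spec.n_somata, 3))
    order = np.argsort(-diams.prod(axis=1))
    max_attempts_per_soma = 2000
    n_voxels = int(np.prod(shape))
    n_placed = 0
    target = spec.target_fill_fraction
    # clearance between somata, per axis: the requested physical gap, but
    # never less than one voxel layer (what 26-connectivity requires so
    # neighbouring somata can never merge into one component)
    gap_vox = np.maximum(1.0, np.ceil(spec.min_gap_um / vox))
    gap_int = gap_vox.astype(int)
    for diam in diams[order]:
        semi_vox = diam / 2.0 / vox
        margin = np.ceil(semi_vox).astype(int) + gap_int
        if any(2 * m + 1 > n for m, n in zip(margin, shape)):
            raise ValueError("a soma plus clearance does not fit in the stack")
        core = _ellipsoid_local(semi_vox)
        # clearance pad = true morphological dilation of the voxelized core
        # (an analytically enlarged ellipsoid does not contain the diagonal
        # neighbours of equatorial core voxels, which would allow touching)
        enlarged = np.pad(core, [(g, g) for g in gap_int])
        enlarged = ndimage.binary_dilation(
            enlarged, structure=np.ones(tuple(2 * g + 1 for g in gap_int), bool)
        )
        for attempt in range(max_attempts_per_soma):
            center = np.array(
                [rng.integers(m, n - m) for m, n in zip(margin, shape)], dtype=int
            )
            placed_box = _place(center, enlarged, shape)
            if placed_box is None:
                continue
            sl_pad, loc_pad = placed_box
            if np.any(occupancy[sl_pad] & loc_pad):
                continue
            sl_core, loc_core = _place(center, core, shape)
            soma_mask[sl_core] |= loc_core
            occupancy[sl_pad] |= loc_pad
            n_placed += 1
            break
        else:
            # rejection sampling stalls near jamming: fall back to an exact
            # search of all centres where the padded soma still fits
            center = _free_center(occupancy, enlarged, margin, rng)
            if center is None:
                continue  # this soma fits nowhere; smaller ones may still fit
            sl_pad, loc_pad = _place(center, enlarged, shape)
            sl_core, loc_core = _place(center, core, shape)
            soma_mask[sl_core] |= loc_core
            occupancy[sl_pad] |= loc_pad
            n_placed += 1
        if target is not None and soma_mask.sum() >= target * n_voxels:
            break
    if target is not None:
        if soma_mask.sum() < target * n_voxels and n_placed < spec.n_somata:
            raise RuntimeError(
                f"jammed at {soma_mask.mean():.3f} fill before reaching the "
                f"target fraction {target}; reduce the target or soma size"
            )
    elif n_placed < spec.n_somata:
        raise RuntimeError(
            f"could not pack {spec.n_somata} somata (placed {n_placed}); "
            "reduce n_somata or soma size"
        )

    # speckles: single voxels or 2-voxel lateral pairs, clear of somata
    speckle_occ = ndimage.binary_dilation(occupancy, iterations=1)
    n_spk = 0
    attempts = 0
    while n_spk < spec.n_speckles and attempts < 200 * max(spec.n_speckles, 1):
        attempts += 1
        z = int(rng.integers(0, shape[0]))
        y = int(rng.integers(0, shape[1] - 1))
        x = int(rng.integers(0, shape[2] - 1))
        pts = [(z, y, x)]
        if rng.random() < 0.5:  # lateral pair, still < 1 um in extent
            if rng.random() < 0.5:
                pts.append((z, y + 1, x))
            else:
                pts.append((z, y, x + 1))
        if any(speckle_occ[p] or speckle_mask[p] for p in pts):
            continue
        for p in pts:
            speckle_mask[p] = True
        n_spk += 1

    # intensity model: multiplicative low-frequency background, bright
    # somata, dim sub-resolution speckles, Poisson photon + Gaussian read noise
    coarse = rng.standard_normal((2, 2, 2))
    smooth = ndimage.zoom(coarse, [s / c for s, c in zip(shape, coarse.shape)], order=1)
    smooth = (smooth - smooth.mean()) / (smooth.std() + 1e-12)
    bg = spec.background_level * np.clip(1.0 + spec.background_mod_frac * smooth, 0.1, None)
    expected = bg.copy()
    expected[soma_mask] = bg[soma_mask] + spec.soma_intensity
    expected[speckle_mask] = bg[speckle_mask] + spec.speckle_intensity_frac * spec.soma_intensity
    counts = rng.poisson(expected).astype(np.float64)
    counts += rng.normal(0.0, spec.read_noise_sd, size=shape)
    data = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)

    truth = IhcTruth(
        soma_mask=soma_mask,
        speckle_mask=speckle_mask,
        n_somata=n_placed,
        tau_fraction=float((soma_mask | speckle_mask).mean()),
    )
    return MicroStack(data, spec.voxel_size_um), truth
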