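"""Voxel-wise statistical maps and dice overlap.

A deliberately small stand-in for an SPM-style analysis: reference-region
scaling of static images, per-voxel two-sample (pooled-variance) or
paired t-maps inside a brain mask, one-sided thresholding in the
direction of interest (TG > WT), and the dice coefficient between binary
maps.  No smoothing is applied by default (an optional Gaussian stage is
provided); no cluster-extent filtering or multiplicity correction is
performed — thresholds are interpreted as "uncorrected", matching how
such maps are typically displayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats

from .images import LabelAtlas, StaticImage

__all__ = [
    "SUVRImage",
    "TStatMap",
    "BinaryMap",
    "scale_by_reference",
    "smooth_image",
    "voxelwise_ttest",
    "threshold_map",
    "dice_coefficient",
]


@dataclass(frozen=True)
class SUVRImage:
    """Static image divided by its reference-VOI mean (that mean becomes 1)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    reference: str

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be 3D")


@dataclass(frozen=True)
class TStatMap:
    """Per-voxel t statistics inside an analysis mask."""

    t: np.ndarray
    df: float
    mask: np.ndarray
    test: str  # "unpaired" | "paired"

    def __post_init__(self):
        if self.t.shape != self.mask.shape:
            raise ValueError("t and mask shapes differ")


@dataclass(frozen=True)
class BinaryMap:
    """Thresholded (or otherwise derived) boolean volume with provenance."""

    mask: np.ndarray
    threshold: float = float("nan")
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def scale_by_reference(img: StaticImage, atlas: LabelAtlas, reference: str) -> SUVRImage:
    """Divide every voxel by the reference-VOI mean.

    Idempotent: rescaling an already-scaled image leaves it unchanged,
    because the reference mean of the output is 1 by construction.
    """
    mask = atlas.mask(reference)
    if not mask.any():
        raise ValueError(f"reference VOI {reference!r} is empty")
    ref_mean = float(np.asarray(img.data[mask], dtype=np.float64).mean())
    if ref_mean <= 0:
        raise ValueError(f"reference VOI {reference!r} has non-positive mean")
    return SUVRImage(img.data / ref_mean, img.voxel_size_mm, reference)


def smooth_image(img: SUVRImage, fwhm_mm: float) -> SUVRImage:
    """Optional Gaussian smoothing stage (FWHM in mm)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return img
    sigma = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v for v in img.voxel_size_mm]
    return SUVRImage(ndimage.gaussian_filter(img.data, sigma), img.voxel_size_mm, img.reference)


def _stack(images: Sequence[SUVRImage | np.ndarray]) -> np.ndarray:
    arrs = [im.data if isinstance(im, SUVRImage) else np.asarray(im, float) for im in images]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError("images are not on a common grid")
    return np.stack(arrs).astype(np.float64)


def voxelwise_ttest(
    group_a: Sequence[SUVRImage | np.ndarray],
    group_b: Sequence[SUVRImage | np.ndarray],
    mask: np.ndarray | BinaryMap,
    paired: bool = False,
) -> TStatMap:
    """Per-voxel t statistic (group_a vs group_b) inside a mask.

    Unpaired: pooled-variance two-sample t with df = n_a + n_b - 2.
    Paired: t on matched differences (requires equal n, matched order),
    df = n - 1.  Voxels with zero variance get t = 0 when the mean
    difference is also zero, +/-inf otherwise.  Outside the mask t is 0.
    """
    m = mask.mask if isinstance(mask, BinaryMap) else np.asarray(mask, bool)
    a, b = _stack(group_a), _stack(group_b)
    if a.shape[1:] != m.shape or b.shape[1:] != m.shape:
        raise ValueError("images and mask are not on a common grid")
    n_a, n_b = a.shape[0], b.shape[0]
    if paired:
        if n_a != n_b:
            raise ValueError("paired test requires equal group sizes (matched order)")
        if n_a < 2:
            raise ValueError("paired test needs n >= 2")
        d = a - b
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        se = sd / np.sqrt(n_a)
        df = float(n_a - 1)
    else:
        if n_a < 2 or n_b < 2:
            raise ValueError("each group needs n >= 2")
        mean = a.mean(axis=0) - b.mean(axis=0)
        var_p = ((n_a - 1) * a.var(axis=0, ddof=1) + (n_b - 1) * b.var(axis=0, ddof=1)) / (
            n_a + n_b - 2
        )
        se = np.sqrt(var_p * (1.0 / n_a + 1.0 / n_b))
        df = float(n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t[np.isnan(t)] = 0.0
    t[~m] = 0.0
    return TStatMap(t, df, m, "paired" if paired else "unpaired")


def threshold_map(tmap: TStatMap, t_thr: float) -> BinaryMap:
    """One-sided suprathreshold mask: voxels with t >= t_thr inside the mask."""
    if not np.isfinite(t_thr):
        raise ValueError("threshold must be finite")
    sel = (tmap.t >= t_thr) & tmap.mask
    p_unc = float(stats.t.sf(t_thr, tmap.df)) if tmap.df > 0 else float("nan")
    return BinaryMap(
        sel,
        threshold=float(t_thr),
        provenance={"test": tmap.test, "df": tmap.df, "p_uncorrected": p_unc},
    )


def dice_coefficient(a: BinaryMap | np.ndarray, b: BinaryMap | np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); 0 when both maps are empty."""
    ma = a.mask if isinstance(a, BinaryMap) else np.asarray(a, bool)
    mb = b.mask if isinstance(b, BinaryMap) else np.asarray(b, bool)
    if ma.shape != mb.shape:
        raise ValueError("maps are not on a common grid")
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((ma & mb).sum()) / denom
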