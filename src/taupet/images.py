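"""Core image containers for dynamic small-animal PET analysis.

A :class:`DynamicImage` is a 4D activity-concentration volume (arbitrary
units) with an explicit frame schedule in minutes post-injection.  A
:class:`LabelAtlas` is an integer-labelled 3D volume, co-registered to the
image grid, that names the volumes of interest (VOIs).  Atlases may define
*composite* VOIs (e.g. ``whole_brain``) as unions of several labels.

All images are assumed to be already registered to a common grid; no
resampling or reorientation is performed here.  Times are minutes, voxel
sizes are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = ["DynamicImage", "StaticImage", "LabelAtlas"]


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _check_frame_schedule(start: np.ndarray, end: np.ndarray) -> None:
    if start.ndim != 1 or start.shape != end.shape or start.size == 0:
        raise ValueError("frame schedule must be two equal-length, non-empty 1D arrays")
    if not np.all(end > start):
        raise ValueError("every frame must have end > start")
    if start.size > 1 and not np.all(start[1:] >= end[:-1]):
        raise ValueError("frames must be strictly increasing and non-overlapping")


@dataclass(frozen=True)
class DynamicImage:
    """4D dynamic PET image: spatial grid x frames, with frame timing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, n_frames)
        Activity concentration per voxel per frame (arbitrary units).
    frame_start_min, frame_end_min : ndarray, shape (n_frames,)
        Frame boundaries in minutes post-injection; strictly increasing
        and non-overlapping.
    voxel_size_mm : tuple of float
        Physical voxel size along (x, y, z).
    """

    data: np.ndarray
    frame_start_min: np.ndarray
    frame_end_min: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "frame_start_min", _as_float_array(self.frame_start_min))
        object.__setattr__(self, "frame_end_min", _as_float_array(self.frame_end_min))
        _check_frame_schedule(self.frame_start_min, self.frame_end_min)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, frame)")
        if self.data.shape[3] != self.frame_start_min.size:
            raise ValueError("number of frames in data and schedule differ")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def frame_mid_min(self) -> np.ndarray:
        return 0.5 * (self.frame_start_min + self.frame_end_min)

    @property
    def frame_duration_min(self) -> np.ndarray:
        return self.frame_end_min - self.frame_start_min

    @property
    def acquisition_span(self) -> tuple[float, float]:
        return float(self.frame_start_min[0]), float(self.frame_end_min[-1])

    # ---------------------------------------------------------------- I/O
    def save(self, path: str | Path) -> None:
        """Write as NIfTI-1 plus a ``.frames.json`` timing sidecar."""
        path = Path(path)
        affine = np.diag([*self.voxel_size_mm, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine), str(path))
        sidecar = {
            "frames": [[float(s), float(e)] for s, e in zip(self.frame_start_min, self.frame_end_min)],
            "units": "min",
        }
        _sidecar_path(path, ".frames.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DynamicImage":
        path = Path(path)
        img = nib.load(str(path))
        meta = json.loads(_sidecar_path(path, ".frames.json").read_text())
        frames = np.asarray(meta["frames"], dtype=float)
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), frames[:, 0], frames[:, 1], vox)


@dataclass(frozen=True)
class StaticImage:
    """A 3D image summed/averaged over a time window (records that window)."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    window_min: tuple[float, float]

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("static image contains non-finite values")
        if self.window_min[1] <= self.window_min[0]:
            raise ValueError("window must satisfy end > start")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        affine = np.diag([*self.voxel_size_mm, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine), str(path))


@dataclass(frozen=True)
class LabelAtlas:
    """Integer-labelled 3D VOI atlas on the image grid.

    ``labels`` uses 0 for background.  ``names`` maps label value to VOI
    name; ``groups`` optionally maps a composite VOI name to a tuple of
    label values (e.g. ``whole_brain`` as the union of all brain labels).
    """

    labels: np.ndarray
    names: Mapping[int, str]
    voxel_size_mm: tuple[float, float, float]
    groups: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative (0 = background)")

    # ------------------------------------------------------------- lookup
    @property
    def name_to_label(self) -> dict[str, int]:
        return {v: k for k, v in self.names.items()}

    def voi_names(self) -> list[str]:
        return list(self.names.values()) + list(self.groups)

    def _labels_for(self, voi: str) -> tuple[int, ...]:
        if voi in self.groups:
            return tuple(self.groups[voi])
        lut = self.name_to_label
        if voi in lut:
            return (lut[voi],)
        raise KeyError(f"VOI {voi!r} not in atlas; known VOIs: {sorted(self.voi_names())}")

    def mask(self, voi: str) -> np.ndarray:
        """Boolean mask for a (possibly composite) VOI name."""
        return np.isin(self.labels, self._labels_for(voi))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def volume_mm3(self, voi: str) -> float:
        """Physical VOI volume: voxel count times voxel volume."""
        return float(self.mask(voi).sum()) * self.voxel_volume_mm3

    def volumes_mm3(self) -> dict[str, float]:
        return {name: self.volume_mm3(name) for name in self.voi_names()}

    # ---------------------------------------------------------------- I/O
    def save(self, path: str | Path) -> None:
        path = Path(path)
        affine = np.diag([*self.voxel_size_mm, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(self.labels, dtype=np.int16), affine), str(path))
        meta = {
            "names": {str(k): v for k, v in self.names.items()},
            "groups": {k: list(v) for k, v in self.groups.items()},
        }
        _sidecar_path(path, ".labels.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LabelAtlas":
        path = Path(path)
        img = nib.load(str(path))
        meta = json.loads(_sidecar_path(path, ".labels.json").read_text())
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            labels=np.asarray(img.dataobj, dtype=np.int32),
            names={int(k): v for k, v in meta["names"].items()},
            voxel_size_mm=vox,
            groups={k: tuple(v) for k, v in meta.get("groups", {}).items()},
        )


def _sidecar_path(path: Path, suffix: str) -> Path:
    """Sidecar path for ``x.nii`` / ``x.nii.gz`` -> ``x<suffix>``."""
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + suffix)
    return path.with_name(name + suffix)
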