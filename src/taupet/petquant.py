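"""Dynamic-PET VOI quantification.

Covers the VOI-level operations of a reference-region SUVR analysis:
frame summation over a time window (duration-weighted mean, with partial
frames weighted by temporal overlap), time-activity-curve (TAC)
extraction, target/reference ratio curves, ratio-stability analysis to
locate the usable SUVR window, SUVR computation, washout metrics
(fraction of peak remaining at given times) and regional uptake relative
to whole brain.

SUVR here is a concentration ratio, so the duration-weighted *mean*
(not sum) is used throughout; any consistent convention cancels in the
ratio.  VOI means are plain voxel-count means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .images import DynamicImage, LabelAtlas, StaticImage

__all__ = [
    "TimeActivityCurve",
    "RatioCurve",
    "SUVRRecord",
    "sum_frames",
    "extract_tac",
    "ratio_tac",
    "find_stable_window",
    "compute_suvr",
    "washout_metrics",
    "relative_uptake",
    "TRACER_DEFAULTS",
]

# Default target/reference/window per tracer: brainstem-to-striatum(+septum)
# over 40-60 min for T807, brainstem-to-cerebellum over 30-60 min for THK5117.
TRACER_DEFAULTS: dict[str, dict] = {
    "t807": {"target": "brainstem", "reference": "striatum_septum", "window": (40.0, 60.0)},
    "thk5117": {"target": "brainstem", "reference": "cerebellum", "window": (30.0, 60.0)},
}


@dataclass(frozen=True)
class TimeActivityCurve:
    """Mean VOI activity per frame vs frame midpoint time."""

    times_min: np.ndarray  # frame midpoints
    values: np.ndarray
    durations_min: np.ndarray
    voi: str

    def __post_init__(self):
        t, v, d = (np.asarray(x, dtype=float) for x in (self.times_min, self.values, self.durations_min))
        if not (t.shape == v.shape == d.shape) or t.ndim != 1:
            raise ValueError("times, values and durations must be equal-length 1D arrays")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame midpoints must be strictly increasing")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "durations_min", d)

    @property
    def n_frames(self) -> int:
        return self.times_min.size


@dataclass(frozen=True)
class RatioCurve:
    """Target/reference ratio per frame."""

    times_min: np.ndarray
    values: np.ndarray
    durations_min: np.ndarray
    target: str
    reference: str


@dataclass(frozen=True)
class SUVRRecord:
    """One animal's SUVR over a window, with grouping metadata."""

    animal_id: str
    genotype: str
    tracer: str
    target: str
    reference: str
    window_min: tuple[float, float]
    value: float

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("SUVR must be positive")
        if self.window_min[1] <= self.window_min[0]:
            raise ValueError("window must satisfy end > start")


def _window_weights(img: DynamicImage, window: tuple[float, float]) -> np.ndarray:
    """Per-frame temporal-overlap weights of a window; errors if disjoint."""
    start, end = float(window[0]), float(window[1])
    if end <= start:
        raise ValueError("window must satisfy end > start")
    overlap = np.minimum(img.frame_end_min, end) - np.maximum(img.frame_start_min, start)
    overlap = np.clip(overlap, 0.0, None)
    if overlap.sum() <= 0:
        span = img.acquisition_span
        raise ValueError(
            f"window {window} does not overlap the acquisition ({span[0]:g}-{span[1]:g} min)"
        )
    return overlap


def sum_frames(img: DynamicImage, window: tuple[float, float]) -> StaticImage:
    """Duration-weighted mean image over a time window.

    Frames partially covered by the window contribute proportionally to
    their temporal overlap, so the result does not depend on how finely
    the schedule subdivides the window.
    """
    w = _window_weights(img, window)
    data = np.tensordot(img.data, w / w.sum(), axes=([3], [0]))
    return StaticImage(data, img.voxel_size_mm, (float(window[0]), float(window[1])))


def extract_tac(img: DynamicImage, atlas: LabelAtlas, voi: str) -> TimeActivityCurve:
    """Per-frame unweighted mean over the VOI's voxels."""
    if atlas.labels.shape != img.shape:
        raise ValueError("atlas and image grids differ")
    mask = atlas.mask(voi)
    if not mask.any():
        raise ValueError(f"VOI {voi!r} is empty on this grid")
    values = np.asarray(img.data[mask], dtype=np.float64).mean(axis=0)
    return TimeActivityCurve(img.frame_mid_min, values, img.frame_duration_min, voi)


def ratio_tac(target: TimeActivityCurve, reference: TimeActivityCurve) -> RatioCurve:
    """Element-wise target/reference ratio on identical frame schedules."""
    if target.times_min.shape != reference.times_min.shape or not np.allclose(
        target.times_min, reference.times_min
    ):
        raise ValueError("target and reference TACs have different frame schedules")
    if np.any(reference.values <= 0):
        raise ValueError("reference TAC has non-positive values; ratio undefined")
    return RatioCurve(
        target.times_min,
        target.values / reference.values,
        target.durations_min,
        target.voi,
        reference.voi,
    )


def find_stable_window(
    rc: RatioCurve, slope_tol_per_min: float = 0.002, min_span_min: float = 20.0
) -> tuple[float, float] | None:
    """Earliest onset from which the ratio curve is flat to the end.

    Scans candidate onsets (frame midpoints, earliest first) and accepts
    the first whose least-squares line over [onset, last frame] has
    ``|slope| <= slope_tol_per_min * mean(ratio over the span)``, with at
    least three points and a span of ``min_span_min``.  Returns
    ``(onset_min, end_min)`` or ``None`` when no window qualifies.
    """
    t, r = rc.times_min, rc.values
    if t.size < 3:
        raise ValueError("ratio curve needs at least 3 frames")
    t_end = t[-1]
    for i in range(t.size - 2):
        if t_end - t[i] < min_span_min:
            break
        tt, rr = t[i:], r[i:]
        slope = np.polyfit(tt, rr, 1)[0]
        if abs(slope) <= slope_tol_per_min * rr.mean():
            return float(t[i]), float(t_end)
    return None


def compute_suvr(
    img: DynamicImage,
    atlas: LabelAtlas,
    target: str,
    reference: str,
    window: tuple[float, float],
    animal_id: str = "",
    genotype: str = "",
    tracer: str = "",
) -> SUVRRecord:
    """SUVR = windowed duration-weighted mean of target over reference.

    By linearity of the VOI mean this equals the ratio of the two VOI
    means of :func:`sum_frames` over the same window.
    """
    w = _window_weights(img, window)
    w = w / w.sum()
    num = float(extract_tac(img, atlas, target).values @ w)
    den = float(extract_tac(img, atlas, reference).values @ w)
    if den <= 0:
        raise ValueError(f"reference VOI {reference!r} has non-positive windowed mean")
    return SUVRRecord(
        animal_id=animal_id,
        genotype=genotype,
        tracer=tracer,
        target=target,
        reference=reference,
        window_min=(float(window[0]), float(window[1])),
        value=num / den,
    )


def washout_metrics(tac: TimeActivityCurve, times_min: Sequence[float]) -> np.ndarray:
    """Percent of peak activity remaining at the requested times.

    Values between frame midpoints are linearly interpolated; the peak is
    the maximum frame value.  Requested times must lie within the TAC's
    midpoint support.
    """
    times = np.asarray(times_min, dtype=float)
    lo, hi = tac.times_min[0], tac.times_min[-1]
    if np.any(times < lo) or np.any(times > hi):
        raise ValueError(f"requested times outside TAC support [{lo:g}, {hi:g}] min")
    peak = tac.values.max()
    if peak <= 0:
        raise ValueError("TAC has no positive peak")
    return 100.0 * np.interp(times, tac.times_min, tac.values) / peak


def relative_uptake(
    region: TimeActivityCurve, whole_brain: TimeActivityCurve, time_min: float
) -> float:
    """Region/whole-brain ratio at the frame covering ``time_min``."""
    if region.times_min.shape != whole_brain.times_min.shape or not np.allclose(
        region.times_min, whole_brain.times_min
    ):
        raise ValueError("region and whole-brain TACs have different frame schedules")
    starts = region.times_min - region.durations_min / 2.0
    ends = region.times_min + region.durations_min / 2.0
    idx = np.nonzero((starts <= time_min) & (time_min <= ends))[0]
    if idx.size == 0:
        raise ValueError(f"no frame covers t = {time_min:g} min")
    i = int(idx[0])
    if whole_brain.values[i] <= 0:
        raise ValueError("whole-brain value non-positive at the requested frame")
    return float(region.values[i] / whole_brain.values[i])
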