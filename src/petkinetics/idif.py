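"""Image-derived input function from a cylindrical aorta ROI.

The descending aorta runs roughly axially, so the ROI is a cylinder: a
voxel belongs to it when its center's transverse-plane (x-y) distance to
the centerline, evaluated at the voxel's z, is within the radius (4 mm by
default). Membership is a pure voxel-center test — no partial-volume
weighting — and the cylinder's z extent is the centerline's z range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    DynamicImage,
    FrameSchedule,
    InputFunction,
    TimeActivityCurve,
    as_input_function,
)

__all__ = ["Centerline", "cylinder_mask", "extract_tac", "auc", "resample_if"]


@dataclass(frozen=True)
class Centerline:
    """Ordered vessel centerline as world-mm points (x, y, z)."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("centerline must be an (n, 3) array of world-mm points")
        if pts.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive centerline points must be distinct")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)


def cylinder_mask(
    centerline: Centerline,
    radius_mm: float,
    geometry: DynamicImage,
) -> np.ndarray:
    """Binary mask of the cylindrical ROI around a (near-axial) centerline.

    A voxel is included iff its center lies within the centerline's z
    range and its in-plane distance to the centerline position at that z
    (linear interpolation along z) is at most ``radius_mm``.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    pts = centerline.points
    order = np.argsort(pts[:, 2], kind="stable")
    pts = pts[order]
    if np.any(np.diff(pts[:, 2]) <= 0):
        raise ValueError(
            "centerline z coordinates must be strictly monotone for an "
            "axial cylinder ROI"
        )
    x, y, z = geometry.voxel_centers_world()
    zmin, zmax = pts[0, 2], pts[-1, 2]
    in_z = (z >= zmin - 1e-9) & (z <= zmax + 1e-9)
    cx = np.interp(z, pts[:, 2], pts[:, 0])
    cy = np.interp(z, pts[:, 2], pts[:, 1])
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    mask = in_z & (d2 <= radius_mm**2 + 1e-9)
    if not mask.any():
        raise ValueError(
            f"cylinder ROI is empty: radius {radius_mm} mm, centerline z in "
            f"[{zmin:g}, {zmax:g}] mm, image z in [{z.min():g}, {z.max():g}] "
            f"mm with spacing {geometry.spacing_mm} — is the centerline "
            "inside the field of view?"
        )
    return mask


def extract_tac(
    data: DynamicImage, mask: np.ndarray, label: str = "C_T"
) -> TimeActivityCurve:
    """Per-frame unweighted mean over masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape3d:
        raise ValueError(
            f"mask shape {mask.shape} does not match image grid {data.shape3d}"
        )
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask selects no voxels")
    values = data.data[mask].mean(axis=0, dtype=np.float64)
    return TimeActivityCurve(data.schedule, values, label=label)


def _samples_with_origin(tac) -> tuple[np.ndarray, np.ndarray]:
    """(mid-time, value) pairs with (0, 0) prepended when needed.

    Activity is zero before injection, so when the first mid-time is
    positive a (0, 0) sample anchors integration and interpolation.
    """
    t, v = tac.mid_times_min, tac.values
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
    return t, v


def auc(tac, t0: float = 0.0, t1: float = 60.0) -> float:
    """Trapezoidal area under a TAC between ``t0`` and ``t1`` minutes.

    Integrates over the (mid-time, value) samples, prepending (0, 0) when
    the window starts at injection. The window may extend past the last
    mid-time up to the scan end; there the last sample is held constant.
    """
    schedule: FrameSchedule = tac.schedule
    end_min = schedule.end_time_s / 60.0
    if not (0 <= t0 < t1 <= end_min + 1e-9):
        raise ValueError(
            f"integration window [{t0}, {t1}] min must lie within the scan "
            f"[0, {end_min:g}] min with t0 < t1"
        )
    t, v = _samples_with_origin(tac)
    if t1 > t[-1]:
        t = np.concatenate([t, [t1]])
        v = np.concatenate([v, [v[-1]]])
    lo = max(t0, t[0])
    grid = np.unique(np.concatenate([[lo, t1], t[(t > lo) & (t < t1)]]))
    if grid.size < 2:
        raise ValueError("fewer than 2 samples in the integration window")
    return float(np.trapezoid(np.interp(grid, t, v), grid))


def resample_if(source: InputFunction, target: FrameSchedule) -> InputFunction:
    """Resample an input function onto another protocol's mid-times.

    Linear interpolation through the (0, 0)-prepended source samples;
    target mid-times beyond the last source mid-time hold the last value
    (with a warning). Used to share one reference input function across
    framing protocols.
    """
    source = as_input_function(source)
    t, v = _samples_with_origin(source.tac)
    tt = target.mid_times_min
    if tt[-1] > t[-1] + 1e-9:
        warnings.warn(
            f"target mid-times extend to {tt[-1]:g} min beyond the source's "
            f"last sample at {t[-1]:g} min; holding the last value",
            stacklevel=2,
        )
    vals = np.interp(tt, t, v)
    tac = TimeActivityCurve(target, vals, label=source.tac.label)
    return InputFunction(tac, source.plasma_to_blood_ratio)
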