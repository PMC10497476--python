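"""Frame schedules, time-activity curves, and dynamic-image containers.

The shared data model for dynamic PET kinetic analysis. A scan is
partitioned into contiguous temporal frames; every curve and every 4D
volume carries its :class:`FrameSchedule` so that downstream stages
(rebinning, input-function extraction, Patlak regression) agree on timing.

Conventions
-----------
* Schedules and on-disk formats store time in **seconds**; kinetic math
  (integrals, Patlak normalized time) is done in **minutes**, so that the
  net influx rate Ki comes out in mL/min/cm^3.
* A frame value is the time-average of the decay-corrected activity
  concentration over the frame, attributed to the frame **mid-time** for
  all regression and integration.
* Frame intervals are half-open, ``[start, start + duration)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "InputFunction",
    "DynamicImage",
    "PRESET_SPECS",
    "PRESET_NAMES",
    "make_schedule",
    "preset_protocol",
    "frame_midtimes",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True, eq=False)
class FrameSchedule:
    """Ordered, contiguous partition of a dynamic scan into temporal frames.

    Parameters
    ----------
    starts : array-like
        Frame start times in seconds; the first frame starts at 0.
    durations : array-like
        Frame durations in seconds, strictly positive.
    name : str, optional
        Protocol label (e.g. ``"P-100f"``).
    """

    starts: np.ndarray
    durations: np.ndarray
    name: str | None = None

    def __post_init__(self):
        starts = _as_float_array(self.starts, "starts")
        durations = _as_float_array(self.durations, "durations")
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if starts.size != durations.size:
            raise ValueError("starts and durations must have equal length")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be strictly positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frames must be sorted by start time")
        if starts[0] != 0:
            raise ValueError(f"first frame must start at 0 s, got {starts[0]} s")
        gaps = starts[1:] - (starts[:-1] + durations[:-1])
        if np.any(np.abs(gaps) > 1e-9):
            i = int(np.argmax(np.abs(gaps) > 1e-9))
            raise ValueError(
                f"frames must be contiguous and non-overlapping; frame {i + 1} "
                f"starts at {starts[i + 1]} s but frame {i} ends at "
                f"{starts[i] + durations[i]} s"
            )
        starts.setflags(write=False)
        durations.setflags(write=False)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        """Frame end times in seconds (exclusive bounds)."""
        return self.starts + self.durations

    @property
    def end_time_s(self) -> float:
        """Total covered time in seconds."""
        return float(self.starts[-1] + self.durations[-1])

    @property
    def edges(self) -> np.ndarray:
        """The n_frames + 1 frame boundaries in seconds."""
        return np.concatenate([self.starts, [self.end_time_s]])

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    def to_spec(self) -> list[tuple[int, float]]:
        """Run-length encode the schedule as ``[(count, duration_s), ...]``."""
        spec: list[tuple[int, float]] = []
        for d in self.durations:
            if spec and spec[-1][1] == d:
                spec[-1] = (spec[-1][0] + 1, spec[-1][1])
            else:
                spec.append((1, float(d)))
        return spec

    def same_timing(self, other: "FrameSchedule", tol: float = 1e-9) -> bool:
        return (
            self.n_frames == other.n_frames
            and np.allclose(self.starts, other.starts, atol=tol)
            and np.allclose(self.durations, other.durations, atol=tol)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = f" {self.name!r}" if self.name else ""
        return (
            f"FrameSchedule({self.n_frames} frames{label}, "
            f"0-{self.end_time_s:g} s)"
        )


#: The six framing protocols compared in the 0-60 min FDG study, as
#: ``[(frame count, frame duration in seconds), ...]``. All cover 3600 s.
PRESET_SPECS: dict[str, list[tuple[int, float]]] = {
    "P-100f": [(30, 1), (30, 5), (10, 12), (5, 60), (25, 120)],
    "P-61f": [(30, 2), (6, 10), (8, 30), (4, 60), (5, 120), (8, 300)],
    "P-48f": [(12, 5), (6, 10), (8, 30), (8, 60), (8, 120), (6, 300)],
    "P-29f": [(6, 10), (2, 30), (6, 60), (5, 120), (4, 180), (6, 300)],
    "P-19f": [(6, 10), (3, 180), (10, 300)],
    "P-12f": [(6, 10), (1, 540), (5, 600)],
}

PRESET_NAMES: tuple[str, ...] = tuple(PRESET_SPECS)


def make_schedule(
    spec: Sequence[tuple[int, float]], name: str | None = None
) -> FrameSchedule:
    """Build a contiguous schedule from ``[(count, duration_s), ...]``.

    >>> make_schedule([(30, 1), (30, 5), (10, 12), (5, 60), (25, 120)]).n_frames
    100
    """
    if len(spec) == 0:
        raise ValueError("schedule spec is empty")
    durations = []
    for count, dur in spec:
        if int(count) != count or count < 1:
            raise ValueError(f"frame count must be a positive integer, got {count}")
        if dur <= 0:
            raise ValueError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    durations = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations, name=name)


def preset_protocol(name: str) -> FrameSchedule:
    """Return one of the six printed framing protocols by name."""
    try:
        spec = PRESET_SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown framing protocol {name!r}; valid presets are "
            f"{', '.join(PRESET_NAMES)}"
        ) from None
    return make_schedule(spec, name=name)


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Frame mid-times in minutes (strictly increasing)."""
    return schedule.mid_times_min


@dataclass(frozen=True, eq=False)
class TimeActivityCurve:
    """Per-frame mean decay-corrected activity concentration (kBq/mL).

    ``label`` tags the curve's role: tissue concentration ``"C_T"`` or
    blood/plasma ``"C_P"``. Negative values are permitted (they occur in
    noisy low-uptake regions) but are flagged via
    :attr:`has_negative_values`.
    """

    schedule: FrameSchedule
    values: np.ndarray
    label: str = "C_T"

    def __post_init__(self):
        values = _as_float_array(self.values, "values")
        if values.size != self.schedule.n_frames:
            raise ValueError(
                f"curve has {values.size} values but schedule has "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("curve values must be finite")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        if np.any(values < 0):
            logger.info(
                "TAC %r contains %d negative values (noise)",
                self.label,
                int(np.sum(values < 0)),
            )

    @property
    def has_negative_values(self) -> bool:
        return bool(np.any(self.values < 0))

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.schedule.mid_times_min


@dataclass(frozen=True, eq=False)
class InputFunction:
    """A blood-pool TAC playing the role of the plasma input C_P.

    For FDG at late times the plasma-to-whole-blood ratio is close to one,
    so the default leaves the image-derived blood curve unscaled.
    """

    tac: TimeActivityCurve
    plasma_to_blood_ratio: float = 1.0

    def __post_init__(self):
        if self.plasma_to_blood_ratio <= 0:
            raise ValueError("plasma_to_blood_ratio must be positive")

    @property
    def schedule(self) -> FrameSchedule:
        return self.tac.schedule

    @property
    def values(self) -> np.ndarray:
        """Plasma concentration per frame (blood values times the ratio)."""
        return self.tac.values * self.plasma_to_blood_ratio

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.tac.mid_times_min


def as_input_function(cp) -> InputFunction:
    """Coerce a TAC or InputFunction into an :class:`InputFunction`."""
    if isinstance(cp, InputFunction):
        return cp
    if isinstance(cp, TimeActivityCurve):
        return InputFunction(cp)
    raise TypeError(f"expected TimeActivityCurve or InputFunction, got {type(cp)!r}")


@dataclass(eq=False)
class DynamicImage:
    """4D decay-corrected activity volume with timing and world geometry.

    ``data`` is ``(x, y, z, frame)`` in kBq/mL; ``affine`` maps 0-based
    voxel indices (voxel-center convention) to world millimetres.
    """

    data: np.ndarray
    schedule: FrameSchedule
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x,y,z,frame), got {self.data.ndim}D")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"data has {self.data.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_centers_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-mm coordinates of every voxel center, as three 3D arrays."""
        nx, ny, nz = self.shape3d
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        A = self.affine
        x = A[0, 0] * ii + A[0, 1] * jj + A[0, 2] * kk + A[0, 3]
        y = A[1, 0] * ii + A[1, 1] * jj + A[1, 2] * kk + A[1, 3]
        z = A[2, 0] * ii + A[2, 1] * jj + A[2, 2] * kk + A[2, 3]
        return x, y, z
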