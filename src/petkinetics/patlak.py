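"""Patlak graphical analysis: ROI fits and voxelwise parametric maps.

For an irreversibly trapped tracer, once the reversible compartments have
equilibrated (t >= t*), the tissue-to-plasma ratio is linear in
"normalized time":

    C_T(t) / C_P(t) = Ki * (int_0^t C_P dtau) / C_P(t) + intercept

The slope Ki is the net influx rate [mL/min/cm^3]; the intercept mixes
blood volume and the reversible distribution volume [mL/cm^3]. Fits are
ordinary (unweighted) least squares over frames with mid-time >= t*; the
plasma integral uses all frames from time zero.

Because the regressor x depends only on the input function, the voxelwise
solve shares one design across the volume and reduces to closed-form
per-voxel slope/intercept — that vectorized path is validated elsewhere
against a plain per-ROI OLS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .core import (
    DynamicImage,
    InputFunction,
    TimeActivityCurve,
    as_input_function,
)
from .idif import extract_tac, resample_if

logger = logging.getLogger(__name__)

__all__ = [
    "PatlakResult",
    "patlak_transform",
    "patlak_fit",
    "patlak_voxelwise",
    "roi_patlak",
]


@dataclass(frozen=True)
class PatlakResult:
    """Patlak fit output: Ki and intercept maps or scalars plus fit SSE.

    ``ki`` is in mL/min/cm^3 (multiply by 1000 for uL/min/cm^3),
    ``intercept`` in mL/cm^3, ``sse`` the sum of squared residuals over
    the fitted frames.
    """

    ki: np.ndarray | float
    intercept: np.ndarray | float
    sse: np.ndarray | float
    t_star: float
    n_frames_used: int

    def __post_init__(self):
        if self.n_frames_used < 2:
            raise ValueError("a Patlak fit needs at least 2 frames")

    @property
    def ki_ul(self):
        """Ki in uL/min/cm^3, the scale conventionally tabulated."""
        return np.asarray(self.ki) * 1000.0 if np.ndim(self.ki) else self.ki * 1000.0


def _plasma_design(cp: InputFunction, t_star: float, prepend_zero: bool):
    """Shared Patlak regressor from the input function.

    Returns (used-frame indices, x values, plasma values at used frames).
    Frames with non-positive plasma values cannot be normalized and are
    dropped with a warning.
    """
    t = cp.mid_times_min
    v = cp.values
    if t[0] > 0:
        # the integral always runs from injection (t = 0): anchor it with a
        # zero sample, or with the first value held back when suppressed
        v0 = 0.0 if prepend_zero else v[0]
        t_int = np.concatenate([[0.0], t])
        v_int = np.concatenate([[v0], v])
        integral = cumulative_trapezoid(v_int, t_int, initial=0.0)[1:]
    else:
        integral = cumulative_trapezoid(v, t, initial=0.0)
    used = t >= t_star
    bad = used & (v <= 0)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} frame(s) with non-positive plasma "
            "activity from the Patlak fit",
            stacklevel=3,
        )
        used &= v > 0
    if used.sum() < 2:
        raise ValueError(
            f"fewer than 2 usable frames at or after t* = {t_star} min"
        )
    idx = np.nonzero(used)[0]
    x = integral[idx] / v[idx]
    return idx, x, v[idx]


def patlak_transform(
    ct: TimeActivityCurve,
    cp,
    t_star: float = 10.0,
    *,
    prepend_zero: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Patlak coordinates (x, y) for frames with mid-time >= t*.

    x = int_0^t C_P / C_P(t) (normalized time, minutes), y = C_T / C_P
    (unitless). The plasma integral runs from time zero over all frames,
    with a (0, 0) sample prepended unless ``prepend_zero`` is False. If
    ``cp`` is on a different schedule it is resampled to the tissue one.
    """
    cp = as_input_function(cp)
    if not cp.schedule.same_timing(ct.schedule):
        cp = resample_if(cp, ct.schedule)
    idx, x, v = _plasma_design(cp, t_star, prepend_zero)
    y = ct.values[idx] / v
    return x, y


def patlak_fit(x, y) -> tuple[float, float, float]:
    """Unweighted least-squares line through Patlak points.

    Returns ``(Ki, intercept, sse)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("degenerate fit: all x values are equal")
    ki = float(xc @ y) / sxx
    intercept = float(y.mean() - ki * x.mean())
    resid = y - (ki * x + intercept)
    return ki, intercept, float(resid @ resid)


def patlak_voxelwise(
    data: DynamicImage,
    cp,
    t_star: float = 10.0,
    mask: np.ndarray | None = None,
    *,
    fill_value: float = 0.0,
    prepend_zero: bool = True,
    clip_negative_ki: bool = False,
) -> PatlakResult:
    """Voxelwise Patlak parametric maps (Ki, intercept, SSE).

    The regressor x is shared across voxels (it depends only on C_P), so
    the per-voxel OLS has a closed form and is fully vectorized. Voxels
    outside ``mask`` are set to ``fill_value`` (negative Ki values are
    kept unless ``clip_negative_ki``).
    """
    cp = as_input_function(cp)
    if not cp.schedule.same_timing(data.schedule):
        cp = resample_if(cp, data.schedule)
    idx, x, v = _plasma_design(cp, t_star, prepend_zero)

    shape = data.shape3d
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape does not match image grid")
        vox = data.data[mask][:, idx].astype(np.float64)
    else:
        vox = data.data[..., idx].reshape(-1, idx.size).astype(np.float64)

    y = vox / v  # (n_voxels, n_used_frames)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    ki = (y @ xc) / sxx
    intercept = y.mean(axis=1) - ki * x.mean()
    resid = y - (ki[:, None] * x[None, :] + intercept[:, None])
    sse = np.einsum("ij,ij->i", resid, resid)
    if clip_negative_ki:
        ki = np.maximum(ki, 0.0)

    def _to_map(vals):
        if mask is None:
            return vals.reshape(shape)
        out = np.full(shape, fill_value, dtype=float)
        out[mask] = vals
        return out

    logger.info(
        "voxelwise Patlak: %d voxels, %d/%d frames used (t* = %g min)",
        y.shape[0],
        idx.size,
        data.schedule.n_frames,
        t_star,
    )
    return PatlakResult(
        ki=_to_map(ki),
        intercept=_to_map(intercept),
        sse=_to_map(sse),
        t_star=t_star,
        n_frames_used=int(idx.size),
    )


def roi_patlak(
    data: DynamicImage,
    cp,
    t_star: float,
    label_mask: np.ndarray,
    label: int,
    *,
    prepend_zero: bool = True,
) -> PatlakResult:
    """Patlak fit on the mean TAC of one labeled ROI."""
    label_mask = np.asarray(label_mask)
    roi = label_mask == label
    if not roi.any():
        raise ValueError(f"label {label} selects no voxels")
    ct = extract_tac(data, roi)
    x, y = patlak_transform(ct, cp, t_star, prepend_zero=prepend_zero)
    ki, intercept, sse = patlak_fit(x, y)
    return PatlakResult(
        ki=ki, intercept=intercept, sse=sse, t_star=t_star, n_frames_used=x.size
    )
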