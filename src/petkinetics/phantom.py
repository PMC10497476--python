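"""Synthetic dynamic FDG phantoms with known kinetic ground truth.

Generates desk-scale 4D dynamic PET data in decay-corrected space: an
arterial bolus from a tri-exponential population input model, tissue
curves from the two-tissue irreversible compartment model, Gaussian noise
whose variance scales with activity over frame duration (a surrogate for
count statistics), and an axial blood cylinder standing in for the
descending aorta.

Region net-influx rates (Ki = K1*k3/(k2+k3)) default to typical 60-min
FDG organ values (lesion 23.5, gray matter 36.5, ... muscle 1.6
uL/min/cm^3); the micro-parameters K1, k2, k3 behind each Ki are the
generator's own choices, constrained to k2+k3 within 0.05-1.5 /min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

from .core import (
    DynamicImage,
    FrameSchedule,
    InputFunction,
    TimeActivityCurve,
)

__all__ = [
    "KineticParams",
    "InputFunctionModel",
    "PhantomSpec",
    "GroundTruth",
    "FENG_FDG_DEFAULT",
    "DEFAULT_REGIONS",
    "feng_input",
    "tissue_curve_2ti",
    "frame_average",
    "default_phantom_spec",
    "default_centerline_points",
    "build_phantom",
]


@dataclass(frozen=True)
class KineticParams:
    """Two-tissue irreversible micro-parameters for one region.

    K1 [mL/min/cm^3] is plasma-to-tissue delivery, k2 [1/min] efflux,
    k3 [1/min] trapping (k4 = 0), Vb the fractional blood volume.
    """

    K1: float
    k2: float
    k3: float
    Vb: float = 0.0

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3) < 0:
            raise ValueError("K1, k2, k3 must be non-negative")
        if not 0 <= self.Vb < 1:
            raise ValueError("Vb must lie in [0, 1)")

    @property
    def ki_true(self) -> float:
        """Macro net influx rate K1*k3/(k2+k3) [mL/min/cm^3].

        By continuity convention: equals K1 for pure trapping
        (k2 = k3 = 0) and 0 when k3 = 0 with k2 > 0.
        """
        if self.k2 == 0 and self.k3 == 0:
            return self.K1
        if self.k3 == 0:
            return 0.0
        return self.K1 * self.k3 / (self.k2 + self.k3)

    @property
    def intercept_true(self) -> float:
        """Asymptotic Patlak intercept of the measured curve [mL/cm^3].

        (1-Vb) * K1*k2/(k2+k3)^2 + Vb; the reversible-compartment
        distribution volume plus the blood-volume term.
        """
        beta = self.k2 + self.k3
        if beta == 0:
            return self.Vb
        return (1.0 - self.Vb) * self.K1 * self.k2 / beta**2 + self.Vb

    @property
    def patlak_slope_true(self) -> float:
        """Asymptotic slope of the measured (blood-contaminated) curve.

        The Vb*Cp term adds a constant to C_measured/C_P, so it moves the
        intercept only; the slope is (1-Vb)*Ki.
        """
        return (1.0 - self.Vb) * self.ki_true


@dataclass(frozen=True)
class InputFunctionModel:
    """Tri-exponential arterial bolus model.

    Cp(t) = (A1*t - A2 - A3) e^{-l1 t} + A2 e^{-l2 t} + A3 e^{-l3 t},
    t in minutes; Cp(0) = 0 by construction. A1 in kBq/mL/min, A2 and A3
    in kBq/mL, eigenvalues l1 > l3 >= l2 > 0 in 1/min.
    """

    A1: float
    A2: float
    A3: float
    lam1: float
    lam2: float
    lam3: float

    def __post_init__(self):
        if not (self.lam1 > self.lam3 >= self.lam2 > 0):
            raise ValueError("eigenvalues must satisfy lam1 > lam3 >= lam2 > 0")


#: Synthetic population defaults for an FDG bolus (sharp ~15 s peak,
#: slowly decaying tail). These are the generator's own configuration,
#: not measured patient values.
FENG_FDG_DEFAULT = InputFunctionModel(
    A1=851.1225, A2=21.8798, A3=20.8113, lam1=4.133859, lam2=0.0104, lam3=0.1191
)


def feng_input(t, model: InputFunctionModel = FENG_FDG_DEFAULT) -> np.ndarray:
    """Evaluate the tri-exponential bolus at times ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("input-function times must be non-negative")
    cp = (
        (model.A1 * t - model.A2 - model.A3) * np.exp(-model.lam1 * t)
        + model.A2 * np.exp(-model.lam2 * t)
        + model.A3 * np.exp(-model.lam3 * t)
    )
    return cp


def _expconv(beta: float, t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """(e^{-beta t} conv f)(t) on a (possibly non-uniform) grid.

    Exact for piecewise-linear ``f``: integrates analytically over each
    step, so accuracy is limited only by the sampling of ``f``.
    """
    if beta == 0:
        return cumulative_trapezoid(f, t, initial=0.0)
    out = np.zeros_like(f)
    h = np.diff(t)
    E = np.exp(-beta * h)
    # f linear on [t_n, t_{n+1}]: f = a + b (tau - t_n)
    a = f[:-1]
    b = np.diff(f) / h
    inc = a * (1.0 - E) / beta + b * (h - (1.0 - E) / beta) / beta
    for n in range(h.size):
        out[n + 1] = out[n] * E[n] + inc[n]
    return out


def tissue_curve_2ti(params: KineticParams, cp, t_grid) -> np.ndarray:
    """Measured tissue curve of the two-tissue irreversible model.

    C_tissue = Ki * integral(Cp) + (K1*k2/(k2+k3)) * e^{-(k2+k3)t} conv Cp
    (the exact solution with k4 = 0), then
    C_measured = (1 - Vb) * C_tissue + Vb * Cp.

    Parameters
    ----------
    cp : callable or array
        Plasma input, either a callable of time (minutes) or samples on
        ``t_grid``.
    t_grid : array
        Monotone time grid in minutes starting at 0, sampled at least as
        finely as the structure of ``cp``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a monotone 1D grid")
    if t[0] != 0:
        raise ValueError("t_grid must start at 0")
    cp_vals = np.asarray(cp(t) if callable(cp) else cp, dtype=float)
    if cp_vals.shape != t.shape:
        raise ValueError("cp samples must align with t_grid")

    beta = params.k2 + params.k3
    int_cp = cumulative_trapezoid(cp_vals, t, initial=0.0)
    if beta == 0:
        # pure trapping limit: C_tissue = K1 * integral(Cp)
        c_tissue = params.K1 * int_cp
    else:
        c_tissue = params.ki_true * int_cp + (
            params.K1 * params.k2 / beta
        ) * _expconv(beta, t, cp_vals)
    return (1.0 - params.Vb) * c_tissue + params.Vb * cp_vals


def frame_average(curve, schedule: FrameSchedule, *, t=None, max_step_s: float = 0.05):
    """Time-average a continuous curve over each frame of a schedule.

    ``curve`` is either a callable of time in **minutes**, or an array of
    samples at times ``t`` (minutes). Each frame is integrated with the
    composite trapezoid rule on an internal sub-grid of at most
    ``max_step_s`` second steps (0.05 s by default, fine enough to hold
    the first-second bolus rise to well under 0.1% error).
    """
    if callable(curve):
        f = curve
        support_end_min = math.inf
    else:
        if t is None:
            raise ValueError("sampled curves require the time grid `t`")
        ts = np.asarray(t, dtype=float)
        ys = np.asarray(curve, dtype=float)
        if ts.shape != ys.shape:
            raise ValueError("curve samples and t must align")
        support_end_min = float(ts[-1])

        def f(x):
            return np.interp(x, ts, ys)

    if schedule.end_time_s / 60.0 > support_end_min + 1e-9:
        raise ValueError(
            f"schedule extends to {schedule.end_time_s} s but the curve is "
            f"only defined up to {support_end_min * 60:g} s"
        )
    out = np.empty(schedule.n_frames)
    for i, (s, d) in enumerate(zip(schedule.starts, schedule.durations)):
        n = max(2, int(math.ceil(d / max_step_s)) + 1)
        sub = np.linspace(s, s + d, n) / 60.0
        out[i] = np.trapezoid(f(sub), sub) / (d / 60.0)
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of a labeled dynamic phantom.

    ``labels`` is a 3D integer map; every nonzero label except
    ``blood_label`` must appear in ``region_params``. The blood region
    carries the arterial input itself. Noise per voxel and frame is
    Gaussian with standard deviation
    ``alpha * sqrt(max(C, c_floor) / duration_s)``.
    """

    labels: np.ndarray
    region_params: dict[int, KineticParams]
    blood_label: int
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 2.886)
    input_model: InputFunctionModel = FENG_FDG_DEFAULT
    noise_alpha: float = 0.0
    c_floor: float = 0.01
    smoothing_fwhm_mm: float | None = None
    seed: int = 0
    region_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D integer map")
        present = set(np.unique(labels).tolist()) - {0}
        if self.blood_label not in present:
            raise ValueError(f"blood label {self.blood_label} absent from label map")
        missing = present - {self.blood_label} - set(self.region_params)
        if missing:
            raise ValueError(f"labels without kinetic parameters: {sorted(missing)}")
        if self.noise_alpha < 0:
            raise ValueError("noise_alpha must be non-negative")
        object.__setattr__(self, "labels", labels)

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[0, 0], A[1, 1], A[2, 2] = self.spacing_mm
        return A


@dataclass(frozen=True)
class GroundTruth:
    """Voxel maps of the true kinetic parameters behind a phantom.

    ``ki`` carries Ki = K1*k3/(k2+k3) per region; ``patlak_slope`` the
    asymptotic slope (1-Vb)*Ki of the measured (blood-contaminated)
    curve; ``intercept`` the asymptotic Patlak intercept.
    """

    ki: np.ndarray
    intercept: np.ndarray
    patlak_slope: np.ndarray


# Region Ki targets in mL/min/cm^3 (x1000 = uL/min/cm^3) with the chosen
# delivery K1 and efflux k2; k3 follows from k3 = Ki*k2/(K1 - Ki).
_REGION_TABLE = {
    # name: (label, Ki, K1, k2, Vb)
    "lesion": (2, 0.0235, 0.102, 0.30, 0.05),
    "gray_matter": (3, 0.0365, 0.102, 0.13, 0.04),
    "white_matter": (4, 0.0116, 0.054, 0.109, 0.03),
    "lung": (5, 0.0009, 0.020, 0.30, 0.15),
    "liver": (6, 0.0037, 0.600, 0.90, 0.20),
    "spleen": (7, 0.0045, 0.400, 0.80, 0.20),
    "bone_marrow": (8, 0.0098, 0.100, 0.25, 0.05),
    "kidney": (9, 0.0055, 0.300, 0.60, 0.20),
    "muscle": (10, 0.0016, 0.030, 0.20, 0.03),
}

BLOOD_LABEL = 1


def _params_from_row(ki: float, K1: float, k2: float, vb: float) -> KineticParams:
    k3 = ki * k2 / (K1 - ki)
    return KineticParams(K1=K1, k2=k2, k3=k3, Vb=vb)


DEFAULT_REGIONS: dict[int, KineticParams] = {
    label: _params_from_row(ki, K1, k2, vb)
    for (label, ki, K1, k2, vb) in _REGION_TABLE.values()
}

DEFAULT_REGION_NAMES: dict[int, str] = {BLOOD_LABEL: "blood"} | {
    row[0]: name for name, row in _REGION_TABLE.items()
}


def _paint_ellipsoid(labels, center, semi, value):
    idx = np.indices(labels.shape)
    d = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    labels[d <= 1.0] = value


def default_phantom_spec(
    shape: tuple[int, int, int] = (32, 32, 48),
    *,
    noise_alpha: float = 0.5,
    seed: int = 0,
    smoothing_fwhm_mm: float | None = None,
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 2.886),
) -> PhantomSpec:
    """Default desk-scale body phantom.

    A straight 2-voxel-radius blood cylinder runs the full axial extent
    through the grid center (descending-aorta analog); nine ellipsoidal
    organ regions and one spherical lesion surround it. Positions scale
    with ``shape`` so smaller grids remain valid.
    """
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)

    # fractional (center, semi-axis) layout on the reference 32x32x48 grid
    layout = {
        "lesion": ((25 / 32, 24 / 32, 10 / 48), (3 / 32, 3 / 32, 4 / 48)),
        "gray_matter": ((8 / 32, 16 / 32, 40 / 48), (5 / 32, 5 / 32, 5 / 48)),
        "white_matter": ((24 / 32, 16 / 32, 40 / 48), (4 / 32, 4 / 32, 5 / 48)),
        "lung": ((7 / 32, 8 / 32, 24 / 48), (5 / 32, 5 / 32, 6 / 48)),
        "liver": ((7 / 32, 8 / 32, 8 / 48), (5 / 32, 5 / 32, 6 / 48)),
        "spleen": ((7 / 32, 24 / 32, 8 / 48), (3 / 32, 3 / 32, 4 / 48)),
        "bone_marrow": ((25 / 32, 8 / 32, 24 / 48), (2 / 32, 2 / 32, 8 / 48)),
        "kidney": ((25 / 32, 8 / 32, 8 / 48), (3 / 32, 3 / 32, 4 / 48)),
        "muscle": ((7 / 32, 24 / 32, 24 / 48), (4 / 32, 4 / 32, 6 / 48)),
    }
    dims = np.array(shape, dtype=float)
    for name, (cfrac, sfrac) in layout.items():
        center = np.array(cfrac) * dims
        semi = np.maximum(np.array(sfrac) * dims, 1.0)
        _paint_ellipsoid(labels, center, semi, _REGION_TABLE[name][0])

    # axial blood cylinder through the in-plane center, 2-voxel radius
    cx, cy = nx / 2, ny / 2
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    blood2d = (ii - cx) ** 2 + (jj - cy) ** 2 <= 2.0**2
    labels[blood2d, :] = BLOOD_LABEL

    return PhantomSpec(
        labels=labels,
        region_params=dict(DEFAULT_REGIONS),
        blood_label=BLOOD_LABEL,
        spacing_mm=spacing_mm,
        noise_alpha=noise_alpha,
        smoothing_fwhm_mm=smoothing_fwhm_mm,
        seed=seed,
        region_names=dict(DEFAULT_REGION_NAMES),
    )


def default_centerline_points(spec: PhantomSpec) -> np.ndarray:
    """World-mm points along the phantom's blood cylinder axis."""
    nx, ny, nz = spec.labels.shape
    k = np.arange(nz, dtype=float)
    pts = np.column_stack(
        [np.full(nz, nx / 2), np.full(nz, ny / 2), k, np.ones(nz)]
    )
    return (spec.affine @ pts.T).T[:, :3]


def _fwhm_to_sigma_vox(fwhm_mm: float, spacing_mm) -> np.ndarray:
    return fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / np.asarray(spacing_mm)


def build_phantom(
    spec: PhantomSpec,
    schedule: FrameSchedule,
    *,
    fine_dt_s: float = 0.25,
) -> tuple[DynamicImage, GroundTruth, InputFunction]:
    """Generate a 4D dynamic phantom on a framing schedule.

    Each voxel's frame values are the frame time-averages of its region's
    continuous model curve, plus activity- and duration-dependent Gaussian
    noise; the blood region carries the arterial input directly. Returns
    the dynamic image, the ground-truth parameter maps, and the true
    (noise-free, frame-averaged) input function.
    """
    labels = spec.labels
    present = [int(v) for v in np.unique(labels) if v != 0]

    # continuous model curves on a fine grid, then frame averages
    t_fine = np.arange(0.0, schedule.end_time_s + fine_dt_s, fine_dt_s) / 60.0
    cp_fine = feng_input(t_fine, spec.input_model)
    region_frames: dict[int, np.ndarray] = {}
    for lab in present:
        if lab == spec.blood_label:
            fine = cp_fine
        else:
            fine = tissue_curve_2ti(spec.region_params[lab], cp_fine, t_fine)
        region_frames[lab] = frame_average(fine, schedule, t=t_fine)

    nF = schedule.n_frames
    shape = labels.shape
    # gather region curves into the 4D volume via a label-index lookup
    lut = np.zeros((max(present) + 1, nF), dtype=np.float32)
    for lab in present:
        lut[lab] = region_frames[lab]
    img = lut[labels]  # (x, y, z, F) float32

    if spec.noise_alpha > 0:
        rng = np.random.default_rng(spec.seed)
        sd_lut = spec.noise_alpha * np.sqrt(
            np.maximum(lut, spec.c_floor)
            / schedule.durations.astype(np.float32)[None, :]
        )
        # background voxels (label 0) sit at the activity floor
        sd_lut[0] = spec.noise_alpha * np.sqrt(
            spec.c_floor / schedule.durations.astype(np.float32)
        )
        sd = sd_lut[labels]
        img = img + rng.standard_normal(img.shape, dtype=np.float32) * sd
        del sd

    if spec.smoothing_fwhm_mm:
        sigma = _fwhm_to_sigma_vox(spec.smoothing_fwhm_mm, spec.spacing_mm)
        for j in range(nF):
            img[..., j] = ndimage.gaussian_filter(img[..., j], sigma=sigma)

    ki = np.zeros(shape)
    intercept = np.zeros(shape)
    slope = np.zeros(shape)
    for lab in present:
        m = labels == lab
        if lab == spec.blood_label:
            intercept[m] = 1.0
        else:
            p = spec.region_params[lab]
            ki[m] = p.ki_true
            intercept[m] = p.intercept_true
            slope[m] = p.patlak_slope_true

    dyn = DynamicImage(img, schedule, affine=spec.affine)
    truth = GroundTruth(ki=ki, intercept=intercept, patlak_slope=slope)
    true_if = InputFunction(
        TimeActivityCurve(schedule, region_frames[spec.blood_label], label="C_P")
    )
    return dyn, truth, true_if
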