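"""Readers and writers for NIfTI volumes, timing sidecars, and TAC CSVs.

Formats
-------
* 4D dynamics and 3D maps/labels: NIfTI (.nii / .nii.gz) via nibabel; all
  geometry is taken from the affine, voxel indices are 0-based with
  voxel-center sampling.
* Frame timing: JSON sidecar with ``"FrameTimesStart"`` and
  ``"FrameDuration"`` (seconds, BIDS-PET style).
* TACs / input functions: CSV with columns ``frame_start_s``,
  ``frame_duration_s``, ``value_kBq_per_mL``.
* Centerlines: CSV with columns ``x_mm``, ``y_mm``, ``z_mm``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicImage, FrameSchedule, TimeActivityCurve
from .idif import Centerline

__all__ = [
    "read_timing",
    "write_timing",
    "read_dynamic",
    "write_dynamic",
    "read_map",
    "write_map",
    "read_tac",
    "write_tac",
    "read_centerline",
    "write_centerline",
    "write_provenance",
]

TAC_COLUMNS = ("frame_start_s", "frame_duration_s", "value_kBq_per_mL")
CENTERLINE_COLUMNS = ("x_mm", "y_mm", "z_mm")


def read_timing(path) -> FrameSchedule:
    with open(path) as fh:
        meta = json.load(fh)
    try:
        starts = meta["FrameTimesStart"]
        durations = meta["FrameDuration"]
    except KeyError as e:
        raise ValueError(f"timing sidecar {path} missing key {e}") from None
    return FrameSchedule(starts, durations, name=meta.get("ProtocolName"))


def write_timing(schedule: FrameSchedule, path) -> None:
    meta = {
        "FrameTimesStart": schedule.starts.tolist(),
        "FrameDuration": schedule.durations.tolist(),
    }
    if schedule.name:
        meta["ProtocolName"] = schedule.name
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_dynamic(image_path, timing_path) -> DynamicImage:
    """Load a 4D NIfTI plus its timing sidecar into a DynamicImage."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{image_path} is {data.ndim}D; expected 4D dynamic data")
    schedule = read_timing(timing_path)
    if schedule.n_frames != data.shape[3]:
        raise ValueError(
            f"timing sidecar has {schedule.n_frames} frames but image has "
            f"{data.shape[3]}"
        )
    return DynamicImage(data, schedule, affine=img.affine)


def write_dynamic(dyn: DynamicImage, image_path, timing_path) -> None:
    img = nib.Nifti1Image(np.asarray(dyn.data, dtype=np.float32), dyn.affine)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(image_path))
    write_timing(dyn.schedule, timing_path)


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI map; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D; expected a 3D map")
    return data, img.affine


def write_map(
    data: np.ndarray,
    affine: np.ndarray,
    path,
    *,
    description: str = "",
    units: str | None = None,
    dtype=np.float32,
) -> None:
    """Write a 3D map as NIfTI, recording units in header and sidecar."""
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
    if units is not None:
        sidecar = Path(str(path)).with_suffix("").with_suffix("")
        with open(str(sidecar) + ".json", "w") as fh:
            json.dump({"Units": units, "Description": description}, fh, indent=1)


def read_tac(path, label: str = "C_T") -> TimeActivityCurve:
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"TAC file {path} missing column(s): {', '.join(missing)}")
    for c in TAC_COLUMNS:
        if not np.issubdtype(df[c].dtype, np.number):
            raise ValueError(f"TAC file {path} has non-numeric entries in {c!r}")
    schedule = FrameSchedule(
        df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy()
    )
    return TimeActivityCurve(schedule, df["value_kBq_per_mL"].to_numpy(), label=label)


def write_tac(tac: TimeActivityCurve, path) -> None:
    pd.DataFrame(
        {
            "frame_start_s": tac.schedule.starts,
            "frame_duration_s": tac.schedule.durations,
            "value_kBq_per_mL": tac.values,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_centerline(path) -> Centerline:
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in CENTERLINE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"centerline file {path} missing column(s): {', '.join(missing)}"
        )
    return Centerline(df[list(CENTERLINE_COLUMNS)].to_numpy(dtype=float))


def write_centerline(points: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(points), columns=list(CENTERLINE_COLUMNS)).to_csv(
        path, index=False, float_format="%.10g"
    )


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path, config: dict, **extra) -> None:
    """Record the configuration (and its hash) that produced an output."""
    from . import __version__

    record = {
        "tool": "petkinetics",
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
    }
    record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, default=str)
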