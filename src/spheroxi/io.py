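"""TIFF + JSON sidecar I/O for phase stacks, lifetime maps, and calibrations.

Phase stacks are stored as multi-page TIFF with axis order
``(time, phase_step, row, col)`` plus a JSON sidecar (same basename, ``.json``
extension) declaring the axis order, phase angles, modulation frequency and
timepoints, along with any simulation metadata and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import StackFormatError
from .flim_core import LifetimeImage, PhaseStackSeries
from .oximetry import CalibrationModel

__all__ = [
    "write_stack",
    "read_stack",
    "write_dataset",
    "write_lifetime",
    "read_lifetime",
    "save_calibration",
    "load_calibration",
]

SCHEMA_VERSION = 1


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: PhaseStackSeries, path, extra_metadata: dict | None = None) -> Path:
    """Write a phase-stack series as TIFF plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, stack.intensities.astype(np.float32), photometric="minisblack"
    )
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "axes": "time,phase_step,row,col",
        "shape": list(stack.intensities.shape),
        "phase_angles_rad": stack.phase_angles.tolist(),
        "modulation_frequency_hz": stack.modulation_frequency,
        "timepoints_min": stack.timepoints.tolist(),
    }
    if extra_metadata:
        sidecar.update(extra_metadata)
    _sidecar_path(path).write_text(
        json.dumps(sidecar, cls=_JsonEncoder, indent=1, sort_keys=True)
    )
    return path


def read_stack(path) -> tuple[PhaseStackSeries, dict]:
    """Read a phase-stack TIFF + sidecar back into a validated series.

    Raises :class:`StackFormatError` on a missing sidecar, an axis/shape
    mismatch between sidecar and TIFF pages, or NaN pixels.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise StackFormatError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("axes") != "time,phase_step,row,col":
        raise StackFormatError(f"unsupported axis order {meta.get('axes')!r}")
    data = np.asarray(tifffile.imread(path), dtype=float)
    if list(data.shape) != list(meta["shape"]):
        try:
            data = data.reshape(meta["shape"])
        except ValueError as exc:
            raise StackFormatError(
                f"TIFF shape {data.shape} does not match sidecar shape "
                f"{meta['shape']}"
            ) from exc
    expected_steps = len(meta["phase_angles_rad"])
    if data.shape[1] != expected_steps:
        raise StackFormatError(
            f"sidecar declares {expected_steps} phase steps but TIFF holds "
            f"{data.shape[1]} pages per timepoint"
        )
    if np.isnan(data).any():
        raise StackFormatError("stack contains NaN pixels")
    series = PhaseStackSeries(
        intensities=data,
        phase_angles=np.asarray(meta["phase_angles_rad"]),
        modulation_frequency=meta["modulation_frequency_hz"],
        timepoints=np.asarray(meta["timepoints_min"]),
    )
    return series, meta


def write_dataset(dataset, outdir) -> dict[str, Path]:
    """Write a simulated device dataset (stack + metadata + ground truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack_path = outdir / "stack.tif"
    write_stack(dataset.stack, stack_path, extra_metadata=dataset.metadata())
    return {"stack": stack_path, "sidecar": _sidecar_path(stack_path)}


def write_lifetime(lifetimes: LifetimeImage, path, metadata: dict | None = None) -> Path:
    """Write a lifetime map as 32-bit float TIFF (tau_phase, tau_mod, mask)."""
    path = Path(path)
    planes = np.stack(
        [
            lifetimes.tau_phase.astype(np.float32),
            lifetimes.tau_mod.astype(np.float32),
            lifetimes.valid_mask.astype(np.float32),
        ]
    )
    tifffile.imwrite(path, planes, photometric="minisblack")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "planes": ["tau_phase_ns", "tau_mod_ns", "valid_mask"],
    }
    if metadata:
        sidecar.update(metadata)
    _sidecar_path(path).write_text(json.dumps(sidecar, cls=_JsonEncoder, indent=1, sort_keys=True))
    return path


def read_lifetime(path) -> LifetimeImage:
    planes = tifffile.imread(Path(path)).astype(float)
    return LifetimeImage(
        tau_phase=planes[0], tau_mod=planes[1], valid_mask=planes[2] > 0.5
    )


def save_calibration(calib: CalibrationModel, path, provenance: str = "") -> Path:
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kq_per_pct": calib.kq,
        "tau_n_ns": calib.tau_n,
        "tau_a_ns": calib.tau_a,
        "o2_a_pct": calib.o2_a,
        "tau0_ns": calib.tau0,
        "provenance": provenance,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_calibration(path) -> CalibrationModel:
    meta = json.loads(Path(path).read_text())
    return CalibrationModel(
        kq=meta["kq_per_pct"],
        tau_n=meta["tau_n_ns"],
        tau_a=meta["tau_a_ns"],
        o2_a=meta["o2_a_pct"],
        tau0=meta["tau0_ns"],
    )
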