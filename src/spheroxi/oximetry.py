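"""Stern-Volmer oximetry: quenching-constant calibration and lifetime-to-O2
conversion with empty-chamber reference normalization.

Collisional quenching by molecular oxygen shortens the excited-state lifetime
of the ruthenium dye according to the Stern-Volmer relation

    tau0 / tau = 1 + Kq * [O2],

so oxygen tension follows from a measured lifetime as
``O2 = (tau0/tau - 1) / Kq``.  The quenching constant is calibrated from two
reference lifetimes, nitrogen-flushed (tau_N, 0% O2) and air-equilibrated
(tau_A, ambient O2A):

    Kq = (tau_N - tau_A) / (tau_A * O2A).

During a device run the unquenched lifetime drifts (photoquenching of the
small dye volume under repeated exposure), so tau0 is re-anchored at every
timepoint from the empty reference chambers in the same device: their mean
lifetime tau_E sits at ambient oxygen by construction, hence

    tau0(t) = tau_E(t) * (1 + Kq * 20.9).

This normalization cancels any lifetime drift common to all chambers.

Oxygen tension is expressed in percent of the gas phase throughout (ambient
air = 20.9%); Kq therefore carries per-percent units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .flim_core import LifetimeImage

__all__ = [
    "CalibrationModel",
    "calibrate_kq",
    "o2_from_lifetime",
    "reference_tau0",
    "o2_map",
    "o2_timeseries",
    "AMBIENT_O2_PERCENT",
]

#: Oxygen tension of ambient air, percent of gas phase.
AMBIENT_O2_PERCENT = 20.9


@dataclass(frozen=True)
class CalibrationModel:
    """Stern-Volmer calibration: quenching constant and reference lifetimes.

    Attributes
    ----------
    kq
        Quenching constant, per % O2.
    tau_n, tau_a
        Nitrogen-flushed (0% O2) and air-equilibrated reference lifetimes, ns.
    o2_a
        Ambient oxygen tension of the air reference, % O2.
    tau0
        Unquenched lifetime, ns.  Equals tau_n for the global calibration
        (the relation at O2 = 0 forces it); superseded per-timepoint by
        :func:`reference_tau0` during device analysis.
    """

    kq: float
    tau_n: float
    tau_a: float
    o2_a: float = AMBIENT_O2_PERCENT
    tau0: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.tau0 is None:
            object.__setattr__(self, "tau0", self.tau_n)
        if not (self.tau_n > self.tau_a > 0):
            raise CalibrationError(
                f"need tau_n > tau_a > 0; got tau_n={self.tau_n}, tau_a={self.tau_a}"
            )
        if self.kq <= 0:
            raise CalibrationError(f"quenching constant must be positive; got {self.kq}")

    def with_tau0(self, tau0: float) -> "CalibrationModel":
        return replace(self, tau0=tau0)


def calibrate_kq(tau_n: float, tau_a: float, o2_a: float = AMBIENT_O2_PERCENT) -> CalibrationModel:
    """Calibrate the quenching constant from the two reference lifetimes.

    Parameters
    ----------
    tau_n, tau_a
        Lifetimes (ns) measured with the dye equilibrated against pure
        nitrogen and against ambient air, respectively.
    o2_a
        Oxygen tension of the air reference, % O2 (default 20.9).

    Returns
    -------
    CalibrationModel
        With ``kq = (tau_n - tau_a) / (tau_a * o2_a)`` and ``tau0 = tau_n``.
    """
    if o2_a <= 0:
        raise CalibrationError(f"ambient O2 must be positive; got {o2_a}")
    if not (tau_n > tau_a > 0):
        raise CalibrationError(
            "nitrogen lifetime must exceed air lifetime "
            f"(got tau_n={tau_n} ns, tau_a={tau_a} ns)"
        )
    kq = (tau_n - tau_a) / (tau_a * o2_a)
    return CalibrationModel(kq=kq, tau_n=tau_n, tau_a=tau_a, o2_a=o2_a, tau0=tau_n)


def o2_from_lifetime(tau, tau0: float, calib: CalibrationModel):
    """Invert Stern-Volmer: ``O2 = (tau0/tau - 1) / Kq`` in % O2.

    Negative results (tau > tau0, indicating reference drift or noise) are
    returned as-is, not clipped, so QC can detect reference problems.
    Accepts scalars or arrays; tau <= 0 raises.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr <= 0):
        raise ValueError("lifetime must be positive to convert to oxygen tension")
    o2 = (tau0 / tau_arr - 1.0) / calib.kq
    return float(o2) if np.isscalar(tau) else o2


def reference_tau0(tau_e: float, calib: CalibrationModel) -> float:
    """Per-timepoint unquenched lifetime from the empty-chamber mean.

    ``tau0 = tau_E * (1 + Kq * 20.9)`` — the empty chambers sit at ambient
    oxygen, so their (possibly drifted) mean lifetime pins tau0 for the same
    device at the same timepoint.
    """
    if tau_e <= 0:
        raise ValueError(f"empty-chamber reference lifetime must be positive; got {tau_e}")
    return tau_e * (1.0 + calib.kq * AMBIENT_O2_PERCENT)


def _empty_reference_lifetime(lifetimes: LifetimeImage, chamber_map, interior_fraction: float) -> float:
    """Pixel-weighted mean tau_phase over all empty-chamber interiors."""
    masks = [
        chamber_map.interior_mask(ch.chamber_id, fraction=interior_fraction)
        for ch in chamber_map.chambers
        if ch.occupancy == "empty"
    ]
    if not masks:
        raise CalibrationError(
            "chamber map labels no empty reference chambers; pass "
            "allow_global_tau0=True to fall back to the global calibration"
        )
    mask = np.any(masks, axis=0) & lifetimes.valid_mask
    if not mask.any():
        raise CalibrationError("no valid pixels in empty reference chambers")
    return float(lifetimes.tau_phase[mask].mean())


def o2_map(
    lifetimes: LifetimeImage,
    chamber_map,
    calib: CalibrationModel,
    timepoint_min: float = 0.0,
    *,
    interior_fraction: float = 0.9,
    allow_global_tau0: bool = False,
):
    """Convert a lifetime image to an oxygen map with per-chamber means.

    The reference lifetime tau_E is the pixel-weighted mean of tau_phase over
    all empty-chamber interiors at this timepoint; tau0 follows from
    :func:`reference_tau0` and every valid pixel is converted via
    :func:`o2_from_lifetime`.  Chamber interiors are pixels within
    ``interior_fraction`` of the chamber radius (default 0.9, excluding wall
    artifacts).

    Returns
    -------
    (o2_image, table)
        ``o2_image``: % O2 per pixel, NaN where invalid.  ``table``: one row
        per chamber with columns ``chamber_id, occupancy, timepoint_min,
        mean_o2_pct, n_pixels, n_negative, tau_e_ns, tau0_ns``.
    """
    try:
        tau_e = _empty_reference_lifetime(lifetimes, chamber_map, interior_fraction)
        tau0 = reference_tau0(tau_e, calib)
    except CalibrationError:
        if not allow_global_tau0:
            raise
        tau_e = float("nan")
        tau0 = calib.tau0

    o2_image = np.full(lifetimes.tau_phase.shape, np.nan)
    valid = lifetimes.valid_mask
    o2_image[valid] = (tau0 / lifetimes.tau_phase[valid] - 1.0) / calib.kq

    rows = []
    for ch in chamber_map.chambers:
        mask = chamber_map.interior_mask(ch.chamber_id, fraction=interior_fraction) & valid
        values = o2_image[mask]
        rows.append(
            {
                "chamber_id": ch.chamber_id,
                "occupancy": ch.occupancy,
                "timepoint_min": timepoint_min,
                "mean_o2_pct": float(values.mean()) if values.size else float("nan"),
                "n_pixels": int(values.size),
                "n_negative": int((values < 0).sum()),
                "tau_e_ns": tau_e,
                "tau0_ns": tau0,
            }
        )
    return o2_image, pd.DataFrame(rows)


def o2_timeseries(
    stack,
    chamber_map,
    calib: CalibrationModel,
    *,
    interior_fraction: float = 0.9,
    allow_global_tau0: bool = False,
    system_modulation_depth: float = 1.0,
) -> pd.DataFrame:
    """Per-chamber oxygen trajectories over a whole phase-stack series.

    Runs demodulation, phase-lifetime estimation and :func:`o2_map` at every
    timepoint and concatenates the per-chamber tables.
    """
    from .flim_core import demodulate, lifetime_from_phase

    tables = []
    for t_idx in range(stack.n_timepoints):
        phasor = demodulate(
            stack, t_idx, system_modulation_depth=system_modulation_depth
        )
        lifetimes = lifetime_from_phase(phasor, stack.modulation_frequency)
        _, table = o2_map(
            lifetimes,
            chamber_map,
            calib,
            timepoint_min=float(stack.timepoints[t_idx]),
            interior_fraction=interior_fraction,
            allow_global_tau0=allow_global_tau0,
        )
        tables.append(table)
    return pd.concat(tables, ignore_index=True)
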