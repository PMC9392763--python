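"""ECIS action spectra via the 60%-of-time-zero common action.

A "common action" shared by all wavelengths — a 60% decrease of a scaled,
t0-normalised electrical parameter — defines a per-well time-to-action.
With the band irradiance known, that time converts to a dose, and the
reciprocal dose is the wavelength's efficiency. Mean efficiency per
wavelength, normalised to a visible reference band (400 nm by default),
gives the action spectrum.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from actinospec.dosimetry import dose_at
from actinospec.plate_io import EcisTrace, PlateMap, WellRole
from actinospec.scaling import mean_trace, scale_ecis
from actinospec.viability_spectrum import normalize_spectrum

__all__ = [
    "time_to_threshold",
    "truncate_at_lamp_off",
    "build_action_spectrum",
    "DEFAULT_FRACTION",
    "DEFAULT_FREQUENCY_HZ",
    "DEFAULT_LAMP_OFF_H",
]

logger = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.6
DEFAULT_FREQUENCY_HZ = 16000.0
DEFAULT_LAMP_OFF_H = 68.0


def time_to_threshold(
    trace: EcisTrace,
    parameter: str = "impedance",
    fraction: float = DEFAULT_FRACTION,
    window: tuple[float, float] | None = None,
    direction: str = "down",
) -> float | None:
    """First time a normalised parameter falls to ``fraction`` of its t0 value.

    The crossing is linearly interpolated between the bracketing samples
    (11-min cadence in the study design). The *first* crossing counts even
    if the trace later recovers. Returns ``None`` (censored) if the level is
    never reached inside the window (default: the whole trace).

    ``direction`` selects the action sense: ``"down"`` (the printed 60%
    decrease), ``"up"`` (the same fold change upward, level ``1/fraction`` —
    capacitance can rise on cell loss), or ``"both"`` (earliest of either).
    """
    if direction not in ("down", "up", "both"):
        raise ValueError(f"direction must be 'down', 'up' or 'both', got {direction!r}")
    if not trace.normalized:
        raise ValueError(f"trace {trace.well}: time_to_threshold expects a t0-normalised trace")
    t = trace.time_h
    v = trace.values(parameter)
    if window is not None:
        lo, hi = window
        if hi <= lo:
            raise ValueError(f"empty window [{lo}, {hi}]")
        keep = (t >= lo) & (t <= hi)
        t, v = t[keep], v[keep]
    if len(t) == 0:
        raise ValueError(f"trace {trace.well}: no samples in window")

    def _first_crossing(values: np.ndarray, level: float, downward: bool) -> float | None:
        hit = values <= level if downward else values >= level
        if not hit.any():
            return None
        i = int(np.argmax(hit))
        if i == 0:
            return float(t[0])
        v0, v1 = values[i - 1], values[i]
        return float(t[i - 1] + (v0 - level) / (v0 - v1) * (t[i] - t[i - 1]))

    crossings = []
    if direction in ("down", "both"):
        crossings.append(_first_crossing(v, fraction, downward=True))
    if direction in ("up", "both"):
        crossings.append(_first_crossing(v, 1.0 / fraction, downward=False))
    crossings = [c for c in crossings if c is not None]
    return min(crossings) if crossings else None


def truncate_at_lamp_off(trace: EcisTrace, lamp_off_h: float = DEFAULT_LAMP_OFF_H) -> EcisTrace:
    """Drop samples after the lamp is doused.

    The abrupt post-exposure signal rise (cells re-adhering once the insult
    stops) would otherwise contaminate crossing detection. No-op when the
    trace ends before the cutoff.
    """
    keep = trace.time_h <= lamp_off_h
    if keep.all():
        return trace
    out = trace.replace_values(
        time_h=trace.time_h[keep],
        impedance_ohm=trace.impedance_ohm[keep],
        resistance_ohm=trace.resistance_ohm[keep],
        capacitance_f=trace.capacitance_f[keep],
    )
    out.meta.setdefault("ops", []).append(f"truncate_at_lamp_off({lamp_off_h})")
    return out


def build_action_spectrum(
    traces: Sequence[EcisTrace],
    pmap: PlateMap,
    irradiance_by_well: Mapping[str, float],
    parameter: str = "impedance",
    frequency_hz: float = DEFAULT_FREQUENCY_HZ,
    fraction: float = DEFAULT_FRACTION,
    lamp_off_h: float = DEFAULT_LAMP_OFF_H,
    reference_nm: float = 400.0,
    prescaled: bool = False,
) -> pd.DataFrame:
    """Per-wavelength reciprocal-dose action spectrum from raw ECIS traces.

    Raw exposed traces are scaled between the mean no-cell and mean dark
    control traces of the same plate map (skipped with ``prescaled=True``),
    truncated at lamp-off, and the common-action crossing converted to an
    efficiency ``1/dose`` per well. Wells that never reach the action are
    censored: they contribute to ``n_censored`` and carry no efficiency.
    Wavelength efficiency is the mean over uncensored wells, then normalised
    to ``reference_nm``.
    """
    by_well = {tr.well: tr for tr in traces if tr.frequency_hz == frequency_hz}
    if not by_well:
        raise ValueError(f"no traces at {frequency_hz} Hz")
    roles = {rec.well: rec for rec in pmap}
    if not prescaled:
        nc = [by_well[r.well] for r in pmap.by_role(WellRole.NO_CELL_CONTROL) if r.well in by_well]
        dk = [by_well[r.well] for r in pmap.by_role(WellRole.DARK_CONTROL) if r.well in by_well]
        if not nc or not dk:
            raise ValueError("scaling requires no_cell_control and dark_control traces in the map")
        nc_mean = mean_trace(nc, "no_cell_mean")
        dk_mean = mean_trace(dk, "dark_mean")
    per_well = []
    for rec in pmap.by_role(WellRole.EXPOSED):
        tr = by_well.get(rec.well)
        if tr is None:
            continue
        scaled = tr if prescaled else scale_ecis(tr, nc_mean, dk_mean)
        scaled = truncate_at_lamp_off(scaled, lamp_off_h)
        t_act = time_to_threshold(scaled, parameter, fraction)
        irr = irradiance_by_well[rec.well]
        dose = dose_at(irr, t_act) if t_act is not None else np.nan
        per_well.append(
            {
                "well": rec.well,
                "wavelength_nm": rec.wavelength_nm,
                "time_to_action_h": t_act if t_act is not None else np.nan,
                "dose_j_m2": dose,
                "efficiency": 1.0 / dose if t_act is not None and dose > 0 else np.nan,
                "censored": t_act is None,
            }
        )
    if not per_well:
        raise ValueError("no exposed traces matched the plate map")
    wells = pd.DataFrame(per_well)
    rows = []
    for wl, grp in wells.groupby("wavelength_nm", sort=True):
        ok = grp[~grp["censored"]]
        rows.append(
            {
                "wavelength_nm": wl,
                "mean_time_to_action_h": ok["time_to_action_h"].mean() if len(ok) else np.nan,
                "dose_to_action_j_m2": ok["dose_j_m2"].mean() if len(ok) else np.nan,
                "efficiency": ok["efficiency"].mean() if len(ok) else np.nan,
                "n_wells": int(len(ok)),
                "n_censored": int(grp["censored"].sum()),
            }
        )
    spectrum = pd.DataFrame(rows).set_index("wavelength_nm")
    if spectrum["n_censored"].sum():
        logger.info(
            "censored wells at: %s",
            list(spectrum.index[spectrum["n_censored"] > 0]),
        )
    spectrum = normalize_spectrum(spectrum, reference_nm)
    spectrum.attrs["parameter"] = parameter
    spectrum.attrs["frequency_hz"] = frequency_hz
    spectrum.attrs["per_well"] = wells.to_dict(orient="records")
    return spectrum
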