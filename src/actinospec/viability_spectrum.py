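"""Viability response spectrum: per-wavelength irradiance regressions.

For each wavelength band the scaled viability of every replicate well is
regressed on irradiance (three levels: full, ND 0.2, ND 0.4). The slope
magnitude measures damage efficiency; slopes are squared (all true damage
slopes are negative) so spectra can be drawn on a log axis, then divided
by the efficiency at a visible reference wavelength (405 nm by default).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from actinospec.plate_io import PlateMap, ViabilityPlate, WellRole
from actinospec.scaling import scale_viability_plate

__all__ = [
    "fit_irradiance_slope",
    "slope_to_efficiency",
    "normalize_spectrum",
    "build_viability_spectrum",
    "DEFAULT_REFERENCE_NM",
]

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_NM = 405.0


def fit_irradiance_slope(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Ordinary least squares of scaled viability on irradiance.

    All replicate wells enter as individual points (no pre-averaging).
    Returns (slope, intercept, r_squared). Requires >= 3 points spanning at
    least two distinct irradiances.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError(f"need >= 3 (irradiance, viability) points, got {pts.shape}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("singular design: all irradiances identical")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 0.0
    return float(res.slope), float(res.intercept), r2


def slope_to_efficiency(slope: float) -> tuple[float, str]:
    """Square a regression slope into a non-negative efficiency.

    The sign is recorded before squaring: positive slopes (viability rising
    with irradiance) are flagged ``'protective'`` and are excluded from the
    log-scale spectrum by default — their square would masquerade as
    toxicity.
    """
    if not np.isfinite(slope):
        raise ValueError(f"slope must be finite, got {slope}")
    if slope > 0:
        sign = "protective"
    elif slope < 0:
        sign = "negative"
    else:
        sign = "zero"
    return float(slope) ** 2, sign


def normalize_spectrum(spectrum: pd.DataFrame, reference_nm: float = DEFAULT_REFERENCE_NM) -> pd.DataFrame:
    """Divide the ``efficiency`` column by its value at the reference band.

    The input frame is indexed by ``wavelength_nm``; the output gains (or
    overwrites) ``normalised_efficiency``, with the reference row at exactly
    1. Idempotent when the reference efficiency is already 1.
    """
    if reference_nm not in spectrum.index:
        raise ValueError(f"reference wavelength {reference_nm} nm absent from spectrum")
    ref = spectrum.loc[reference_nm, "efficiency"]
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(f"reference efficiency at {reference_nm} nm is {ref}; cannot normalise")
    out = spectrum.copy()
    out["normalised_efficiency"] = out["efficiency"] / ref
    return out


def build_viability_spectrum(
    plates: Sequence[ViabilityPlate],
    maps: Sequence[PlateMap],
    irradiance_by_well: Sequence[Mapping[str, float]],
    reference_nm: float = DEFAULT_REFERENCE_NM,
    exclude_protective: bool = True,
) -> pd.DataFrame:
    """Scale plates, fit per-wavelength slopes, square and normalise.

    ``irradiance_by_well[i]`` gives the post-ND irradiance (W m^-2) of each
    exposed well on plate i (see :func:`actinospec.dosimetry.well_irradiances`).
    Biological and technical replicates are pooled as regression points.
    Wavelengths observed at fewer than two irradiance levels are excluded
    with a logged warning. Returns a DataFrame indexed by wavelength_nm with
    columns slope, slope_sign, efficiency, normalised_efficiency, n_points,
    r_squared, n_wells, n_censored.
    """
    if not (len(plates) == len(maps) == len(irradiance_by_well)):
        raise ValueError("plates, maps and irradiance_by_well must have equal length")
    points: dict[float, list[tuple[float, float]]] = {}
    for plate, pmap, irr in zip(plates, maps, irradiance_by_well):
        scaled = scale_viability_plate(plate, pmap)
        for rec in pmap.by_role(WellRole.EXPOSED):
            if rec.well in scaled:
                points.setdefault(rec.wavelength_nm, []).append((irr[rec.well], scaled[rec.well]))
    rows = []
    for wl in sorted(points):
        pts = points[wl]
        xs = {round(p[0], 12) for p in pts}
        if len(pts) < 3 or len(xs) < 2:
            logger.warning("wavelength %.0f nm: only %d irradiance level(s); excluded", wl, len(xs))
            continue
        slope, intercept, r2 = fit_irradiance_slope(pts)
        eff, sign = slope_to_efficiency(slope)
        rows.append(
            {
                "wavelength_nm": wl,
                "slope": slope,
                "intercept": intercept,
                "slope_sign": sign,
                "efficiency": eff,
                "n_points": len(pts),
                "r_squared": r2,
                "n_wells": len(pts),
                "n_censored": 0,
            }
        )
    spectrum = pd.DataFrame(rows)
    if spectrum.empty:
        return spectrum.set_index(pd.Index([], name="wavelength_nm")) if spectrum.empty else spectrum
    spectrum = spectrum.set_index("wavelength_nm")
    normed = normalize_spectrum(spectrum, reference_nm)
    if exclude_protective:
        protective = normed["slope_sign"] == "protective"
        normed.loc[protective, "normalised_efficiency"] = np.nan
    return normed
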