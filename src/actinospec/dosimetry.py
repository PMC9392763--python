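"""Dosimetry: ND-filter attenuation, band irradiance and radiant dose.

Units are fixed package-wide: time in hours, irradiance in W m^-2
(band-integrated), dose in J m^-2 (SI seconds; ``dose = E * t_h * 3600``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from actinospec.plate_io import PlateMap, SpectralIrradiance, WellRole

__all__ = ["ExposureDose", "nd_transmittance", "band_irradiance", "dose_at", "well_irradiances"]

SECONDS_PER_HOUR = 3600.0

#: Irradiance levels in the exposure design: full intensity plus two ND filters.
ND_LEVELS = (0.0, 0.2, 0.4)

#: Nominal bandwidth of the bandpass filters (nm).
DEFAULT_BAND_WIDTH_NM = 10.0


@dataclass(frozen=True)
class ExposureDose:
    """Band irradiance and accumulated dose for one exposure condition."""

    wavelength_nm: float
    irradiance_w_m2: float
    duration_h: float
    dose_j_m2: float

    @classmethod
    def from_exposure(cls, wavelength_nm, irradiance_w_m2, duration_h) -> "ExposureDose":
        return cls(
            wavelength_nm,
            irradiance_w_m2,
            duration_h,
            dose_at(irradiance_w_m2, duration_h),
        )


def nd_transmittance(od: float) -> float:
    """Transmitted fraction of a neutral-density filter: ``10**(-od)``.

    Multiplicative in stacked filters; OD 0.2 passes 63.1% (hence one ND
    step is the study's "1.6-fold" intensity change).
    """
    if od < 0:
        raise ValueError(f"optical density must be >= 0, got {od}")
    return float(10.0 ** (-od))


def band_irradiance(spectrum: SpectralIrradiance, centre_nm: float, width_nm: float = DEFAULT_BAND_WIDTH_NM) -> float:
    """Band-integrated irradiance (W m^-2) over ``centre +/- width/2``.

    Trapezoidal integration on the 1-nm grid; the band must lie inside the
    measured spectrum.
    """
    lo, hi = centre_nm - width_nm / 2.0, centre_nm + width_nm / 2.0
    g = spectrum.grid_nm
    if lo < g[0] or hi > g[-1]:
        raise ValueError(f"band [{lo}, {hi}] nm outside spectrum grid [{g[0]}, {g[-1]}] nm")
    fine = np.linspace(lo, hi, max(int(round(hi - lo)) * 4 + 1, 5))
    vals = np.interp(fine, g, spectrum.values_w_m2_nm)
    return float(np.trapezoid(vals, fine))


def dose_at(irradiance_w_m2: float, time_h: float) -> float:
    """Radiant exposure (J m^-2) accumulated under constant irradiance."""
    if irradiance_w_m2 < 0 or time_h < 0:
        raise ValueError("irradiance and time must be >= 0")
    return float(irradiance_w_m2) * float(time_h) * SECONDS_PER_HOUR


def well_irradiances(
    pmap: PlateMap,
    band_irradiance_by_nm: dict[float, float],
) -> dict[str, float]:
    """Per-well irradiance after ND attenuation for the exposed wells.

    ``band_irradiance_by_nm`` maps band centre to full-intensity band
    irradiance (from :func:`band_irradiance` or the synthetic lamp table).
    """
    out = {}
    for rec in pmap.by_role(WellRole.EXPOSED):
        try:
            full = band_irradiance_by_nm[rec.wavelength_nm]
        except KeyError:
            raise KeyError(
                f"no band irradiance for {rec.wavelength_nm} nm (well {rec.well})"
            ) from None
        out[rec.well] = full * nd_transmittance(rec.nd_od)
    return out
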