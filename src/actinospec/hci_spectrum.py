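"""High-content-imaging response spectra from well x feature tables.

Features are averaged per (wavelength, ND) condition, normalised to the
dark control, regressed on irradiance feature-by-feature, and the squared
slopes averaged within a compartment/kernel selection to give a response
spectrum per feature group (all features, per probe compartment, or the
punctate 'spot' texture kernel).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from actinospec.plate_io import FeatureTable, PlateMap, WellRole
from actinospec.viability_spectrum import fit_irradiance_slope, normalize_spectrum

__all__ = [
    "aggregate_wells",
    "normalize_to_dark",
    "fit_feature_slopes",
    "group_spectrum",
    "FeatureCoefficients",
]

logger = logging.getLogger(__name__)

#: Result of :func:`fit_feature_slopes`: wavelength x feature slope matrix
#: (DataFrame indexed by wavelength_nm, columns = feature names) with the
#: feature tags attached as ``attrs['tags']``.
FeatureCoefficients = pd.DataFrame


def aggregate_wells(table: FeatureTable, pmap: PlateMap) -> pd.DataFrame:
    """Mean feature value per (wavelength, ND) condition plus the dark row.

    Rows are indexed by ``(wavelength_nm, nd_od)``; the dark control
    aggregate carries the index ``('dark', 0.0)``. Means skip NaN feature
    values; conditions with zero wells are simply absent. Every exposed well
    in the table must appear in the map.
    """
    roles = {rec.well: rec for rec in pmap}
    unmapped = [w for w in table.values.index if w not in roles]
    if unmapped:
        raise ValueError(f"wells missing from plate map: {unmapped}")
    keys = []
    for well in table.values.index:
        rec = roles[well]
        if rec.role is WellRole.EXPOSED:
            keys.append((rec.wavelength_nm, rec.nd_od))
        elif rec.role is WellRole.DARK_CONTROL:
            keys.append(("dark", 0.0))
        else:
            keys.append(None)
    frame = table.values.copy()
    frame.index = pd.MultiIndex.from_tuples(
        [k if k is not None else ("_drop", np.nan) for k in keys],
        names=["wavelength_nm", "nd_od"],
    )
    frame = frame[frame.index.get_level_values(0) != "_drop"]
    agg = frame.groupby(level=["wavelength_nm", "nd_od"], sort=False).mean()
    # canonical order: numeric wavelengths ascending, then the dark row
    order = sorted(agg.index, key=lambda t: (isinstance(t[0], str), t))
    return agg.loc[order]


def normalize_to_dark(aggregates: pd.DataFrame) -> pd.DataFrame:
    """Express each condition mean as a fraction of the dark-control mean.

    Features whose dark-control mean is zero (or missing) cannot be
    expressed as a fold change and are dropped with a warning.
    """
    darks = aggregates.loc[aggregates.index.get_level_values("wavelength_nm") == "dark"]
    if darks.empty:
        raise ValueError("no dark-control aggregate present")
    dark = darks.mean(axis=0)
    bad = dark.index[(dark == 0) | dark.isna()]
    if len(bad):
        logger.warning("dropping %d feature(s) with zero/NaN dark control: %s", len(bad), list(bad[:5]))
    keep = [c for c in aggregates.columns if c not in set(bad)]
    out = aggregates[keep] / dark[keep]
    return out[out.index.get_level_values("wavelength_nm") != "dark"]


def fit_feature_slopes(
    normalized_aggregates: pd.DataFrame,
    irradiance_by_condition: Mapping[tuple[float, float], float],
    tags: pd.DataFrame | None = None,
) -> FeatureCoefficients:
    """Per-(wavelength, feature) OLS slope of dark-normalised response.

    ``irradiance_by_condition`` maps ``(wavelength_nm, nd_od)`` to the
    irradiance of that condition. Each feature column is fit independently
    with the shared scalar regression (no cross-feature coupling). Returns
    the wavelength x feature slope matrix; tags (if given) ride along in
    ``attrs['tags']``, per-cell n in ``attrs['n_points']``.
    """
    wavelengths = sorted({wl for wl, _ in normalized_aggregates.index})
    rows = {}
    for wl in wavelengths:
        sub = normalized_aggregates.loc[wl]
        if len(sub) < 2:
            logger.warning("wavelength %s: <2 irradiance levels; excluded", wl)
            continue
        x = np.array([irradiance_by_condition[(wl, od)] for od in sub.index])
        slopes = {}
        for col in sub.columns:
            y = sub[col].to_numpy(float)
            pts = list(zip(x, y))
            if len(pts) >= 3:
                slope, _, _ = fit_irradiance_slope(pts)
            else:
                # two levels: slope is the finite difference
                slope = (y[1] - y[0]) / (x[1] - x[0])
            slopes[col] = slope
        rows[wl] = slopes
    coeffs = pd.DataFrame.from_dict(rows, orient="index")
    coeffs.index.name = "wavelength_nm"
    coeffs = coeffs.sort_index()
    if tags is not None:
        coeffs.attrs["tags"] = tags
    return coeffs


def group_spectrum(
    coeffs: FeatureCoefficients,
    tags: pd.DataFrame | None = None,
    compartment: str | None = None,
    kernel: str | None = None,
    reference_nm: float = 405.0,
) -> pd.DataFrame:
    """Response spectrum of a feature group: mean squared slope, normalised.

    ``compartment``/``kernel`` of ``None`` mean "any" (so both None = the
    'all' spectrum). Squaring precedes averaging so opposite-signed feature
    responses reinforce rather than cancel.
    """
    if tags is None:
        tags = coeffs.attrs.get("tags")
    if tags is None:
        raise ValueError("feature tags required (pass tags= or attach attrs['tags'])")
    mask = pd.Series(True, index=tags.index)
    if compartment is not None:
        mask &= tags["compartment"] == compartment
    if kernel is not None:
        mask &= tags["kernel"] == kernel
    selected = [c for c in coeffs.columns if c in mask.index and mask[c]]
    if not selected:
        raise ValueError(
            f"no features match selector compartment={compartment!r}, kernel={kernel!r}"
        )
    sq = coeffs[selected] ** 2
    spectrum = pd.DataFrame(
        {
            "efficiency": sq.mean(axis=1),
            "n_features": len(selected),
            "n_wells": len(selected),
            "n_censored": 0,
        }
    )
    spectrum.index = spectrum.index.astype(float)
    spectrum.index.name = "wavelength_nm"
    return normalize_spectrum(spectrum, reference_nm)
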