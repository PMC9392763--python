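"""Synthetic plate, ECIS and imaging data with planted wavelength effects.

Every generator is a documented forward model whose truth is planted on the
*scaled/normalised* scale and mapped back through the inverse of the scaling
operations, so that parameter-recovery tests exercise the full pipeline
including control scaling. All outputs are bit-reproducible from
(preset, seed).

The ``"paper-profile"`` preset encodes the study's headline effect sizes:
an ECIS efficiency plateau of 100-fold (vs 400 nm) across 320-350 nm rising
beyond 1e4-fold in the UV-B band; viability losses of 10% (350 nm) and 30%
(380 nm) per neutral-density step with a 20% mean UV-A loss at full
irradiance; three latent imaging bands (290-320 / 330-360 / 370-400 nm);
and a 350-nm 'spot'-kernel rise confined to the nucleus, mitochondria and
ROS compartments.

The synthetic lamp emits wavelength-dependent band irradiance (UV-B output
roughly 200-fold below the visible reference band, as for a real
mercury-halide arc source). This is deliberate: with the reference crossing
placed at 60 h, wavelength-independent irradiance would push the planted
1e4-fold UV-B crossing below the 11-min ECIS sampling interval, where no
interpolation could resolve it; spreading the dose range across both
irradiance and time keeps every planted crossing on the measurable grid,
exactly as the real exposure apparatus does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from actinospec.dosimetry import ND_LEVELS, nd_transmittance
from actinospec.plate_io import (
    COMPARTMENTS,
    EcisTrace,
    FeatureTable,
    PlateMap,
    ViabilityPlate,
    WellRecord,
    WellRole,
)

import pandas as pd

__all__ = ["EffectProfile", "preset", "gen_viability_plates", "gen_ecis_traces", "gen_feature_table"]

#: Exposure band centres (nm): 10-nm UVR bands plus the 405 nm visible reference.
WAVELENGTHS = tuple(float(w) for w in range(290, 401, 10)) + (405.0,)
#: Bands measured on the ECIS plate (normalised to 400 nm, per the action spectra).
ECIS_WAVELENGTHS = tuple(float(w) for w in range(290, 401, 10))

#: Synthetic lamp: full-intensity band irradiance (W m^-2) per band centre.
SYNTHETIC_LAMP_W_M2 = {
    **{w: 0.05 for w in (290.0, 300.0, 310.0)},
    **{w: 1.0 for w in (320.0, 330.0, 340.0, 350.0)},
    360.0: 2.0,
    **{w: 10.0 for w in (370.0, 380.0, 390.0, 400.0, 405.0)},
}

#: Raw-scale anchor levels for the inverse scaling maps.
LYSED_RFU = 5000.0
DARK_RFU = 45000.0
ECIS_RAW_LEVELS = {  # (no-cell, dark) per electrical parameter @ 16 kHz
    "impedance_ohm": (350.0, 1800.0),
    "resistance_ohm": (280.0, 1200.0),
    "capacitance_f": (30e-9, 8e-9),
}

_ND_STEP = 1.0 - 10.0 ** (-0.2)  # relative irradiance lost per ND 0.2 step


@dataclass(frozen=True)
class EffectProfile:
    """Planted per-wavelength effect sizes driving all three generators."""

    name: str
    wavelengths: tuple[float, ...]
    viability_slope_rel: dict[float, float]  # % viability per unit relative irradiance
    ecis_efficiency: dict[float, float]  # reciprocal-dose efficiency relative to 400 nm
    ecis_monotonic: frozenset[float]  # wavelengths with monotone (UV-B-like) decline
    biphasic_params: dict[float, dict]  # early-drop depth / plateau end / late rate
    hci_band: dict[float, int]  # latent imaging band id (1..3)
    hci_band_effect: dict[int, float]  # band-level normalised-response slope
    spot_350_flag: bool  # spot-kernel rise at 350 nm outside PI/Cm
    lamp_w_m2: dict[float, float] = field(default_factory=lambda: dict(SYNTHETIC_LAMP_W_M2))
    reference_crossing_h: float = 60.0  # planted time-to-action at 400 nm

    def __post_init__(self) -> None:
        ref = self.ecis_efficiency.get(400.0)
        if ref is None or not np.isclose(ref, 1.0):
            raise ValueError("profile invariant: ecis_efficiency(400 nm) must be 1")
        if any(e <= 0 for e in self.ecis_efficiency.values()):
            raise ValueError("profile invariant: ecis_efficiency must be > 0")
        bands = [self.hci_band[w] for w in sorted(self.hci_band)]
        if any(b2 < b1 for b1, b2 in zip(bands, bands[1:])):
            raise ValueError("profile invariant: hci bands must be contiguous runs")

    def ecis_crossing_h(self, wavelength_nm: float) -> float:
        """Planted time (h) at which the scaled trace reaches 60% of t0."""
        theta = self.ecis_efficiency[400.0] * self.lamp_w_m2[400.0] * self.reference_crossing_h
        return theta / (self.ecis_efficiency[wavelength_nm] * self.lamp_w_m2[wavelength_nm])


def preset(name: str) -> EffectProfile:
    """Named effect profiles: ``paper-profile``, ``null``, ``two-band``."""
    uvb = (290.0, 300.0, 310.0)
    uva2 = (320.0, 330.0, 340.0, 350.0)
    hci_band = {w: (1 if w <= 320 else 2 if w <= 360 else 3) for w in WAVELENGTHS}
    biphasic = {
        w: {"early_depth": 0.25, "plateau_end_h": 45.0, "late_rate": 0.01}
        for w in ECIS_WAVELENGTHS
    }
    if name == "paper-profile":
        d350, d380 = 10.0 / _ND_STEP, 30.0 / _ND_STEP
        # remaining UV-A bands tuned so the mean full-irradiance UV-A
        # (320-400 nm) viability decrease is exactly 20% of control
        d_other = (9 * 20.0 - d350 - d380) / 7.0
        slopes = {w: -90.0 for w in uvb}
        slopes.update({w: -d_other for w in (320.0, 330.0, 340.0, 360.0, 370.0, 390.0, 400.0)})
        slopes.update({350.0: -d350, 380.0: -d380, 405.0: -5.0})
        eff = {w: 1.0e4 for w in uvb}
        eff.update({w: 1.0e2 for w in uva2})
        eff.update({360.0: 10.0, 370.0: 1.0, 380.0: 1.0, 390.0: 1.0, 400.0: 1.0, 405.0: 1.0})
        return EffectProfile(
            name=name,
            wavelengths=WAVELENGTHS,
            viability_slope_rel=slopes,
            ecis_efficiency=eff,
            ecis_monotonic=frozenset(uvb),
            biphasic_params=biphasic,
            hci_band=hci_band,
            hci_band_effect={1: -0.6, 2: -0.3, 3: -0.05},
            spot_350_flag=True,
        )
    if name == "null":
        return EffectProfile(
            name=name,
            wavelengths=WAVELENGTHS,
            viability_slope_rel={w: 0.0 for w in WAVELENGTHS},
            ecis_efficiency={w: 1.0 for w in WAVELENGTHS},
            ecis_monotonic=frozenset(),
            biphasic_params=biphasic,
            hci_band={w: 1 for w in WAVELENGTHS},
            hci_band_effect={1: 0.0},
            spot_350_flag=False,
        )
    if name == "two-band":
        slopes = {w: (-60.0 if w <= 320 else -10.0) for w in WAVELENGTHS}
        eff = {w: (1.0e3 if w <= 320 else 1.0) for w in WAVELENGTHS}
        eff[400.0] = 1.0
        return EffectProfile(
            name=name,
            wavelengths=WAVELENGTHS,
            viability_slope_rel=slopes,
            ecis_efficiency=eff,
            ecis_monotonic=frozenset((290.0, 300.0, 310.0, 320.0)),
            biphasic_params=biphasic,
            hci_band={w: (1 if w <= 320 else 2) for w in WAVELENGTHS},
            hci_band_effect={1: -0.6, 2: -0.1},
            spot_350_flag=False,
        )
    raise ValueError(f"unknown preset {name!r}; expected paper-profile, null or two-band")


def _well_label(i: int) -> str:
    if not 0 <= i < 96:
        raise ValueError("96-well plate exhausted")
    return f"{chr(65 + i // 12)}{i % 12 + 1:02d}"


# ---------------------------------------------------------------------------
# viability


def gen_viability_plates(
    profile: EffectProfile,
    n_plates: int = 3,
    wells_per_condition: int = 4,
    noise_sd_percent: float = 2.0,
    seed: int | None = None,
):
    """Generate viability plates: 3 biological replicates x 4 technical wells.

    Truth on the scaled scale is ``v = 100 + slope(w) * I_rel`` with
    Gaussian noise (percentage points), inverted into raw RFU through the
    planted lysed/dark control levels. The 39 exposure conditions of one
    biological replicate exceed one 96-well plate, so each replicate spans
    two physical plates, each carrying its own lysed and dark control wells.

    Returns ``(plates, maps, irradiance_by_well)`` ready for
    :func:`actinospec.viability_spectrum.build_viability_spectrum`.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    span = DARK_RFU - LYSED_RFU
    conditions = [(w, od) for w in profile.wavelengths for od in ND_LEVELS]
    plates, maps, irradiances = [], [], []
    for rep in range(1, n_plates + 1):
        todo = [(w, od) for (w, od) in conditions for _ in range(wells_per_condition)]
        part = 0
        while todo:
            part += 1
            entries, readings, irr = [], {}, {}
            i = 0
            for _ in range(4):  # controls first
                well = _well_label(i)
                entries.append(WellRecord(well, WellRole.LYSED_CONTROL))
                readings[well] = LYSED_RFU + rng.normal(0.0, noise_sd_percent) / 100.0 * span
                i += 1
            for _ in range(4):
                well = _well_label(i)
                entries.append(WellRecord(well, WellRole.DARK_CONTROL))
                readings[well] = DARK_RFU + rng.normal(0.0, noise_sd_percent) / 100.0 * span
                i += 1
            while todo and i < 96:
                w, od = todo.pop(0)
                well = _well_label(i)
                i_rel = nd_transmittance(od)
                v = 100.0 + profile.viability_slope_rel[w] * i_rel + rng.normal(0.0, noise_sd_percent)
                entries.append(WellRecord(well, WellRole.EXPOSED, w, od))
                readings[well] = LYSED_RFU + v / 100.0 * span
                irr[well] = profile.lamp_w_m2[w] * i_rel
                i += 1
            pid = f"VIA-r{rep}-p{part}"
            plates.append(ViabilityPlate(pid, readings))
            maps.append(PlateMap(entries, plate_id=pid, replicate_id=rep))
            irradiances.append(irr)
    return plates, maps, irradiances


# ---------------------------------------------------------------------------
# ECIS


def _trace_template(
    t: np.ndarray,
    t_cross: float,
    monotonic: bool,
    params: dict,
    lamp_off_h: float,
    with_bump: bool,
) -> np.ndarray:
    """Normalised-truth trace crossing 0.6 exactly at ``t_cross``.

    Monotone (UV-B-like): linear decline to a floor. Biphasic (UV-A-like):
    an early drop, a plateau, and a late decline; when the planted crossing
    precedes the plateau's end the early drop itself carries the trace
    through 0.6 (the rapid-first-hours phenotype), otherwise the late
    decline does. A first-day media-change bump is added only when it cannot
    interact with the crossing, and a post-lamp-off recovery rise is
    appended.
    """
    if monotonic:
        g = np.maximum(0.05, 1.0 - 0.4 * t / t_cross)
    else:
        plateau_end = params["plateau_end_h"]
        if t_cross <= plateau_end:
            low = 0.45
            e_dur = t_cross * (1.0 - low) / 0.4  # linear drop crosses 0.6 at t_cross
            g = np.where(t < e_dur, 1.0 - (1.0 - low) * t / e_dur, low)
            late = params["late_rate"] * np.maximum(t - plateau_end, 0.0)
            g = np.maximum(g - late, 0.02)
        else:
            high = 1.0 - params["early_depth"]  # plateau level, above threshold
            g = np.where(t < 6.0, 1.0 - (1.0 - high) * t / 6.0, high)
            rate = (high - 0.6) / (t_cross - plateau_end)
            g = np.maximum(g - rate * np.maximum(t - plateau_end, 0.0), 0.02)
            if with_bump:
                bump = 0.04 * np.sin(np.clip(t / 24.0, 0.0, 1.0) * np.pi) ** 2
                g = g + bump
    g = g + 0.1 * np.maximum(t - lamp_off_h, 0.0)  # re-adhesion after dousing
    return g


def gen_ecis_traces(
    profile: EffectProfile,
    wells_per_wavelength: int = 4,
    duration_h: float = 72.0,
    interval_min: float = 11.0,
    lamp_off_h: float = 68.0,
    noise_sd: float = 0.02,
    seed: int | None = None,
):
    """Generate one ECIS plate of raw traces at 16 kHz plus controls.

    Exposed wells (full intensity only, as in the impedance arm of the
    study) follow the planted crossing times ``theta / (efficiency x
    irradiance)``; no-cell and dark control wells bracket the scaling range.
    Multiplicative Gaussian noise of relative s.d. ``noise_sd`` is applied
    to every trace. Returns ``(traces, pmap, irradiance_by_well)``.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    entries, traces, irr = [], [], {}
    i = 0

    # noiseless control trajectories; the dark monolayer keeps maturing
    # slowly, and exposed raw traces are built against these same
    # trajectories so that control scaling inverts the forward model exactly
    drift = 1.0 + 0.0004 * t
    nocell_traj = {attr: np.full_like(t, nc) for attr, (nc, dk) in ECIS_RAW_LEVELS.items()}
    dark_traj = {attr: dk * drift for attr, (nc, dk) in ECIS_RAW_LEVELS.items()}

    def _raw_from_g(g: np.ndarray, c0: float) -> dict[str, np.ndarray]:
        return {
            attr: nocell_traj[attr] + c0 * g * (dark_traj[attr] - nocell_traj[attr])
            for attr in ECIS_RAW_LEVELS
        }

    for role, traj in ((WellRole.NO_CELL_CONTROL, nocell_traj), (WellRole.DARK_CONTROL, dark_traj)):
        for _ in range(4):
            well = _well_label(i)
            i += 1
            entries.append(WellRecord(well, role))
            noise = 1.0 + rng.normal(0.0, noise_sd, size=t.shape)
            vals = {attr: traj[attr] * noise for attr in ECIS_RAW_LEVELS}
            traces.append(EcisTrace(well, 16000.0, t.copy(), vals["impedance_ohm"], vals["resistance_ohm"], vals["capacitance_f"]))
    for w in ECIS_WAVELENGTHS:
        t_cross = profile.ecis_crossing_h(w)
        for _ in range(wells_per_wavelength):
            well = _well_label(i)
            i += 1
            entries.append(WellRecord(well, WellRole.EXPOSED, w, 0.0))
            irr[well] = profile.lamp_w_m2[w]
            g = _trace_template(
                t,
                t_cross,
                monotonic=w in profile.ecis_monotonic,
                params=profile.biphasic_params[w],
                lamp_off_h=lamp_off_h,
                with_bump=t_cross > 30.0,
            )
            g = g * (1.0 + rng.normal(0.0, noise_sd, size=t.shape))
            c0 = rng.uniform(0.92, 0.98)
            vals = _raw_from_g(g, c0)
            traces.append(EcisTrace(well, 16000.0, t.copy(), vals["impedance_ohm"], vals["resistance_ohm"], vals["capacitance_f"]))
    pmap = PlateMap(entries, plate_id="ECIS-1", replicate_id=1)
    return traces, pmap, irr


# ---------------------------------------------------------------------------
# high-content imaging


def _feature_schema(n_features: int) -> pd.DataFrame:
    """Deterministic compartment x kernel allocation of the feature columns.

    95 features per compartment (matching the study's 380-variable export):
    20 intensity, 15 each of SER spot/ridge/edge and STAR morphology,
    10 other SER textures and 5 count-type features.
    """
    per_kernel = {
        "intensity": 20,
        "ser_spot": 15,
        "ser_ridge": 15,
        "ser_edge": 15,
        "ser_other": 10,
        "star_morphology": 15,
        "count": 5,
    }
    rows = []
    for comp in COMPARTMENTS:
        for kern, cnt in per_kernel.items():
            for j in range(cnt):
                rows.append((f"{comp}__{kern}__f{j:02d}", comp, kern, f"f{j:02d}"))
    if len(rows) < n_features:
        raise ValueError(f"schema supports at most {len(rows)} features")
    rows = rows[:n_features]
    return pd.DataFrame(
        [r[1:] for r in rows],
        index=[r[0] for r in rows],
        columns=["compartment", "kernel", "name"],
    )


def gen_feature_table(
    profile: EffectProfile,
    n_features: int = 380,
    wells_per_condition: int = 2,
    noise_sd: float = 0.01,
    coeff_noise_sd: float = 0.02,
    seed: int | None = None,
):
    """Generate an imaging plate and the true coefficient matrix.

    Per-feature truth on the dark-normalised scale is
    ``1 + beta(w, f) * I_rel`` with
    ``beta = band_effect(band(w)) + loading(f) + noise``; 'spot'-kernel
    features of the nucleus/mitochondria/ROS compartments respond 0.4 more
    steeply at 350 nm when the profile's spot flag is set (PI/Cm spot
    features do not), so their squared-slope spectra peak there. Raw well values are the truth times a feature-specific
    dark baseline with multiplicative noise. Two technical wells per
    condition keep the 13 x 3 condition grid plus dark controls within one
    96-well plate.

    Returns ``(table, pmap, irradiance_by_condition, truth)`` where
    ``truth`` is the planted wavelength x feature slope matrix including a
    ``'blank'`` control row of pure noise.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    tags = _feature_schema(n_features)
    cols = list(tags.index)
    loading = rng.normal(0.0, 0.05, size=n_features)
    # each latent band damages through its own mechanism, i.e. carries a
    # band-specific feature signature on top of its scalar mean effect —
    # band offsets along one shared direction alone would be a degenerate
    # (collinear) geometry no clustering method could referee; a profile
    # with a single band (no planted effect) carries no signature
    bands = sorted(set(profile.hci_band.values()))
    band_signature = {
        b: (rng.normal(0.0, 0.25, size=n_features) if len(bands) > 1 else np.zeros(n_features))
        for b in bands
    }
    beta = {}
    for w in profile.wavelengths:
        band = profile.hci_band[w]
        b = profile.hci_band_effect[band] + band_signature[band] + loading + rng.normal(
            0.0, coeff_noise_sd, size=n_features
        )
        if profile.spot_350_flag and w == 350.0:
            spot = (tags["kernel"] == "ser_spot") & (tags["compartment"] != "pi_cm")
            b = b - 0.4 * spot.to_numpy()
        beta[w] = b
    truth = pd.DataFrame(beta, index=cols).T
    truth.index.name = "wavelength_nm"
    truth.loc["blank"] = rng.normal(0.0, coeff_noise_sd, size=n_features)
    truth.attrs["tags"] = tags

    dark_base = 1000.0 * np.exp(rng.normal(0.0, 0.5, size=n_features))
    entries, rows, index = [], [], []
    i = 0
    for _ in range(4):
        well = _well_label(i)
        i += 1
        entries.append(WellRecord(well, WellRole.DARK_CONTROL))
        rows.append(dark_base * (1.0 + rng.normal(0.0, noise_sd, size=n_features)))
        index.append(well)
    irr_by_condition = {}
    for w in profile.wavelengths:
        for od in ND_LEVELS:
            i_rel = nd_transmittance(od)
            # HCI regressions run on the relative-irradiance axis (fraction of
            # full intensity): the three ND conditions share it across
            # wavelengths, so planted coefficients are recovered on their own
            # scale and the latent band structure survives into clustering.
            irr_by_condition[(w, od)] = i_rel
            for _ in range(wells_per_condition):
                well = _well_label(i)
                i += 1
                entries.append(WellRecord(well, WellRole.EXPOSED, w, od))
                norm = 1.0 + truth.loc[w].to_numpy() * i_rel
                rows.append(dark_base * norm * (1.0 + rng.normal(0.0, noise_sd, size=n_features)))
                index.append(well)
    values = pd.DataFrame(rows, index=index, columns=cols)
    table = FeatureTable(values, tags)
    pmap = PlateMap(entries, plate_id="HCI-1", replicate_id=1)
    return table, pmap, irr_by_condition, truth
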