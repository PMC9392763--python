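"""Tabular I/O and core domain types shared by every pipeline stage.

All interchange formats are plain UTF-8 CSV (gzip accepted by ``.gz``
extension, handled transparently by pandas). Well labels follow the 96-well
convention: row letter A–H plus zero-padded column 01–12 (``A01`` … ``H12``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "WellRole",
    "WellRecord",
    "PlateMap",
    "EcisTrace",
    "ViabilityPlate",
    "FeatureTable",
    "SpectralIrradiance",
    "COMPARTMENTS",
    "KERNELS",
    "read_plate_map",
    "write_plate_map",
    "read_ecis_long",
    "write_ecis_long",
    "read_viability_plate",
    "write_viability_plate",
    "read_feature_table",
    "write_feature_table",
    "read_spectrum",
    "write_spectrum_csv",
]


class FormatError(ValueError):
    """A file violated the interchange format or a domain-type invariant."""


_WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")

#: Default ECIS sampling interval (hours); the instrument records every 11 min.
ECIS_INTERVAL_H = 11.0 / 60.0

COMPARTMENTS = ("nucleus", "mitochondria", "ros", "pi_cm")
KERNELS = (
    "intensity",
    "ser_spot",
    "ser_ridge",
    "ser_edge",
    "ser_other",
    "star_morphology",
    "count",
)


def _check_well(label: str) -> str:
    if not _WELL_RE.match(label):
        raise FormatError(f"invalid well label {label!r} (expected A01..H12)")
    return label


class WellRole(str, Enum):
    """Role of a well in the exposure design."""

    EXPOSED = "exposed"
    DARK_CONTROL = "dark_control"
    LYSED_CONTROL = "lysed_control"
    NO_CELL_CONTROL = "no_cell_control"
    MEDIA_ONLY = "media_only"


@dataclass(frozen=True)
class WellRecord:
    """One well of the exposure plate map.

    ``wavelength_nm`` is the bandpass-filter centre (10-nm bands, 290–405 nm)
    and is present iff the well is exposed; ``nd_od`` is the optical density
    of the neutral-density filter in the light path (0 for full intensity).
    """

    well: str
    role: WellRole
    wavelength_nm: float | None = None
    nd_od: float = 0.0

    def __post_init__(self) -> None:
        _check_well(self.well)
        if self.nd_od < 0:
            raise FormatError(f"well {self.well}: nd_od must be >= 0, got {self.nd_od}")
        if self.role is WellRole.EXPOSED:
            if self.wavelength_nm is None:
                raise FormatError(f"well {self.well}: exposed well lacks wavelength_nm")
            if not (290.0 <= self.wavelength_nm <= 405.0):
                raise FormatError(
                    f"well {self.well}: wavelength {self.wavelength_nm} nm outside [290, 405]"
                )
        elif self.wavelength_nm is not None:
            raise FormatError(
                f"well {self.well}: role {self.role.value} must not carry a wavelength"
            )


@dataclass
class PlateMap:
    """Assignment of every used well to (wavelength band, ND filter, role)."""

    entries: list[WellRecord]
    plate_id: str = "plate"
    replicate_id: int = 1

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.entries:
            if rec.well in seen:
                raise FormatError(f"duplicate well {rec.well} in plate {self.plate_id}")
            seen.add(rec.well)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def by_role(self, role: WellRole) -> list[WellRecord]:
        return [r for r in self.entries if r.role is role]

    def record(self, well: str) -> WellRecord:
        for r in self.entries:
            if r.well == well:
                return r
        raise KeyError(f"well {well} not in plate {self.plate_id}")

    def wavelengths(self) -> list[float]:
        """Sorted distinct exposed wavelengths on the plate."""
        return sorted({r.wavelength_nm for r in self.by_role(WellRole.EXPOSED)})


@dataclass
class EcisTrace:
    """Per-well ECIS time series at one measurement frequency.

    Electrical values are positive for raw traces; scaled/normalised traces
    (see :mod:`actinospec.scaling`) are unitless and may reach zero or dip
    below it under noise — ``validate`` only enforces positivity when
    ``normalized`` is False.
    """

    well: str
    frequency_hz: float
    time_h: np.ndarray
    impedance_ohm: np.ndarray
    resistance_ohm: np.ndarray
    capacitance_f: np.ndarray
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    _PARAMS = {
        "impedance": "impedance_ohm",
        "resistance": "resistance_ohm",
        "capacitance": "capacitance_f",
    }

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        for attr in ("impedance_ohm", "resistance_ohm", "capacitance_f"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        n = len(self.time_h)
        for attr in ("impedance_ohm", "resistance_ohm", "capacitance_f"):
            if len(getattr(self, attr)) != n:
                raise FormatError(f"trace {self.well}: ragged sample arrays")
        if n and np.any(np.diff(self.time_h) <= 0):
            raise FormatError(f"trace {self.well}: time not strictly increasing")
        if not self.normalized:
            for attr in ("impedance_ohm", "resistance_ohm", "capacitance_f"):
                if n and np.any(getattr(self, attr) <= 0):
                    raise FormatError(f"trace {self.well}: non-positive {attr} value")

    def values(self, parameter: str) -> np.ndarray:
        try:
            return getattr(self, self._PARAMS[parameter])
        except KeyError:
            raise ValueError(
                f"unknown parameter {parameter!r}; expected one of {sorted(self._PARAMS)}"
            ) from None

    @property
    def n_samples(self) -> int:
        return len(self.time_h)

    def replace_values(self, **arrays: np.ndarray) -> "EcisTrace":
        kwargs = dict(
            well=self.well,
            frequency_hz=self.frequency_hz,
            time_h=self.time_h.copy(),
            impedance_ohm=self.impedance_ohm,
            resistance_ohm=self.resistance_ohm,
            capacitance_f=self.capacitance_f,
            normalized=self.normalized,
            meta=dict(self.meta),
        )
        kwargs.update(arrays)
        return EcisTrace(**kwargs)


@dataclass
class ViabilityPlate:
    """Raw endpoint fluorescence (RFU, Ex 520/Em 580) per well."""

    plate_id: str
    readings: dict[str, float]

    def __post_init__(self) -> None:
        for well, value in self.readings.items():
            _check_well(well)
            if value < 0:
                raise FormatError(f"plate {self.plate_id}, well {well}: negative RFU {value}")


@dataclass
class FeatureTable:
    """Well x feature matrix of imaging features with compartment/kernel tags.

    ``values`` is indexed by well label; ``tags`` is indexed by the column
    names of ``values`` with columns ``compartment``, ``kernel``, ``name``.
    """

    values: pd.DataFrame
    tags: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.tags.index]
        if missing:
            raise FormatError(f"untagged feature columns: {missing}")
        bad_comp = self.tags[~self.tags["compartment"].isin(COMPARTMENTS)]
        if len(bad_comp):
            raise FormatError(f"unknown compartment tags: {sorted(set(bad_comp['compartment']))}")
        bad_kern = self.tags[~self.tags["kernel"].isin(KERNELS)]
        if len(bad_kern):
            raise FormatError(f"unknown kernel tags: {sorted(set(bad_kern['kernel']))}")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, compartment: str | None = None, kernel: str | None = None) -> list[str]:
        """Feature columns matching a compartment and/or kernel filter."""
        mask = pd.Series(True, index=self.tags.index)
        if compartment is not None:
            mask &= self.tags["compartment"] == compartment
        if kernel is not None:
            mask &= self.tags["kernel"] == kernel
        return [c for c in self.values.columns if mask[c]]


@dataclass
class SpectralIrradiance:
    """Source spectrum on a uniform 1-nm wavelength grid (W m^-2 nm^-1)."""

    grid_nm: np.ndarray
    values_w_m2_nm: np.ndarray

    def __post_init__(self) -> None:
        self.grid_nm = np.asarray(self.grid_nm, dtype=float)
        self.values_w_m2_nm = np.asarray(self.values_w_m2_nm, dtype=float)
        if self.grid_nm.ndim != 1 or len(self.grid_nm) != len(self.values_w_m2_nm):
            raise FormatError("spectrum grid and values must be 1-D and equal length")
        if len(self.grid_nm) >= 2:
            steps = np.diff(self.grid_nm)
            if np.any(steps <= 0):
                raise FormatError("spectrum grid must be strictly increasing")
            if not np.allclose(steps, 1.0, atol=1e-9):
                raise FormatError("spectrum grid must be uniform at 1 nm spacing")
        if np.any(self.values_w_m2_nm < 0):
            raise FormatError("spectral irradiance values must be >= 0")


# ---------------------------------------------------------------------------
# plate maps


def read_plate_map(path) -> PlateMap:
    """Read a plate map CSV with columns well, role, wavelength_nm, nd_od.

    Roles are parsed case-insensitively; wavelength/nd_od may be blank for
    control wells. Optional columns plate_id and replicate_id (constant per
    file) are honoured.
    """
    df = pd.read_csv(path, dtype={"well": str, "role": str})
    required = {"well", "role", "wavelength_nm", "nd_od"}
    if not required.issubset(df.columns):
        raise FormatError(f"plate map {path}: missing columns {sorted(required - set(df.columns))}")
    entries = []
    for i, row in df.iterrows():
        role_txt = str(row["role"]).strip().lower()
        try:
            role = WellRole(role_txt)
        except ValueError:
            raise FormatError(f"plate map {path} row {i}: unknown role {row['role']!r}") from None
        wl = row["wavelength_nm"]
        wl = None if pd.isna(wl) else float(wl)
        od = row["nd_od"]
        od = 0.0 if pd.isna(od) else float(od)
        entries.append(WellRecord(str(row["well"]).strip(), role, wl, od))
    plate_id = str(df["plate_id"].iloc[0]) if "plate_id" in df.columns else "plate"
    rep = int(df["replicate_id"].iloc[0]) if "replicate_id" in df.columns else 1
    return PlateMap(entries, plate_id=plate_id, replicate_id=rep)


def write_plate_map(pmap: PlateMap, path) -> None:
    rows = [
        {
            "well": r.well,
            "role": r.role.value,
            "wavelength_nm": r.wavelength_nm,
            "nd_od": r.nd_od,
            "plate_id": pmap.plate_id,
            "replicate_id": pmap.replicate_id,
        }
        for r in pmap.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ECIS


def read_ecis_long(path, capacitance_unit: str = "F") -> list[EcisTrace]:
    """Read a long-format ECIS export into one trace per (well, frequency).

    Columns: time_h, well, frequency_hz, z_ohm, r_ohm, c_farad. Vendors
    exporting capacitance in nF are accommodated with
    ``capacitance_unit="nF"``.
    """
    if capacitance_unit not in ("F", "nF"):
        raise ValueError("capacitance_unit must be 'F' or 'nF'")
    df = pd.read_csv(path)
    required = {"time_h", "well", "frequency_hz", "z_ohm", "r_ohm", "c_farad"}
    if not required.issubset(df.columns):
        raise FormatError(f"ECIS file {path}: missing columns {sorted(required - set(df.columns))}")
    scale_c = 1e-9 if capacitance_unit == "nF" else 1.0
    traces = []
    for (well, freq), grp in df.groupby(["well", "frequency_hz"], sort=True):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy(float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise FormatError(f"ECIS file {path}: duplicated timestamps in well {well} @ {freq} Hz")
        traces.append(
            EcisTrace(
                well=str(well),
                frequency_hz=float(freq),
                time_h=t,
                impedance_ohm=grp["z_ohm"].to_numpy(float),
                resistance_ohm=grp["r_ohm"].to_numpy(float),
                capacitance_f=grp["c_farad"].to_numpy(float) * scale_c,
            )
        )
    return traces


def write_ecis_long(traces: Iterable[EcisTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "time_h": tr.time_h,
                    "well": tr.well,
                    "frequency_hz": tr.frequency_hz,
                    "z_ohm": tr.impedance_ohm,
                    "r_ohm": tr.resistance_ohm,
                    "c_farad": tr.capacitance_f,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# viability plates


def read_viability_plate(path) -> ViabilityPlate:
    """Read a viability plate CSV with columns well, rfu (optional plate_id)."""
    df = pd.read_csv(path, dtype={"well": str})
    if not {"well", "rfu"}.issubset(df.columns):
        raise FormatError(f"viability file {path}: expected columns well, rfu")
    if df["well"].duplicated().any():
        dups = sorted(df.loc[df["well"].duplicated(), "well"])
        raise FormatError(f"viability file {path}: duplicate wells {dups}")
    plate_id = str(df["plate_id"].iloc[0]) if "plate_id" in df.columns else "plate"
    return ViabilityPlate(plate_id, dict(zip(df["well"], df["rfu"].astype(float))))


def write_viability_plate(plate: ViabilityPlate, path) -> None:
    pd.DataFrame(
        {
            "well": list(plate.readings),
            "rfu": list(plate.readings.values()),
            "plate_id": plate.plate_id,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature tables

_TAG_RE = re.compile(r"^(?P<compartment>[a-z_]+)__(?P<kernel>[a-z_]+)__(?P<name>.+)$")


def _parse_feature_tag(column: str) -> tuple[str, str, str] | None:
    m = _TAG_RE.match(column)
    if not m:
        return None
    comp, kern = m.group("compartment"), m.group("kernel")
    if comp not in COMPARTMENTS or kern not in KERNELS:
        return None
    return comp, kern, m.group("name")


def read_feature_table(path, sidecar=None, sep: str | None = None) -> FeatureTable:
    """Read a wide well x feature table (tab- or comma-delimited).

    Tags are resolved from the ``compartment__kernel__name`` column-name
    prefix first; a sidecar CSV (columns column, compartment, kernel, name)
    covers columns without the prefix. Untaggable columns are a format
    error naming every offending column.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt", ".txt.gz")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str).map(_check_well)
    side = {}
    if sidecar is not None:
        sdf = pd.read_csv(sidecar, dtype=str)
        for _, row in sdf.iterrows():
            side[row["column"]] = (row["compartment"], row["kernel"], row["name"])
    records, untagged = {}, []
    for col in df.columns:
        tag = _parse_feature_tag(col) or side.get(col)
        if tag is None:
            untagged.append(col)
        else:
            records[col] = tag
    if untagged:
        raise FormatError(f"feature table {path}: untaggable columns {untagged}")
    tags = pd.DataFrame.from_dict(
        records, orient="index", columns=["compartment", "kernel", "name"]
    )
    return FeatureTable(df.astype(float), tags)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table using the tag-prefix column convention."""
    renamed = {
        c: f"{table.tags.loc[c, 'compartment']}__{table.tags.loc[c, 'kernel']}__{table.tags.loc[c, 'name']}"
        for c in table.values.columns
    }
    out = table.values.rename(columns=renamed)
    out.index.name = "well"
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt", ".txt.gz")) else ","
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# spectra


def read_spectrum(path) -> SpectralIrradiance:
    """Read a 2-column spectroradiometer CSV (wavelength_nm, irradiance)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"spectrum file {path}: expected 2 columns")
    return SpectralIrradiance(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_spectrum_csv(spectrum_result: pd.DataFrame, path) -> None:
    """Write a response/action spectrum result table.

    Emits wavelength_nm, efficiency, normalised_efficiency, n_wells,
    n_censored (missing diagnostic columns are filled with 0), at full
    precision so that a round trip is lossless to >= 12 significant digits.
    """
    out = spectrum_result.reset_index() if spectrum_result.index.name == "wavelength_nm" else spectrum_result.copy()
    for col in ("n_wells", "n_censored"):
        if col not in out.columns:
            out[col] = 0
    cols = ["wavelength_nm", "efficiency", "normalised_efficiency", "n_wells", "n_censored"]
    missing = [c for c in cols[:3] if c not in out.columns]
    if missing:
        raise FormatError(f"spectrum result lacks columns {missing}")
    out[cols].to_csv(path, index=False, float_format="%.15g")
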