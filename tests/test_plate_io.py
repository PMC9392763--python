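import gzip

import numpy as np
import pandas as pd
import pytest

from actinospec import plate_io
from actinospec.plate_io import (
    FormatError,
    PlateMap,
    SpectralIrradiance,
    ViabilityPlate,
    WellRecord,
    WellRole,
)
from actinospec.synthetic_data import gen_feature_table, preset


def _write(path, text):
    path.write_text(text)
    return path


class TestPlateMap:
    def test_parses_exposed_and_control_rows(self, tmp_path):
        p = _write(
            tmp_path / "map.csv",
            "well,role,wavelength_nm,nd_od\nA01,exposed,350,0.2\nH12,dark_control,,\n",
        )
        pmap = plate_io.read_plate_map(p)
        rec = pmap.record("A01")
        assert (rec.role, rec.wavelength_nm, rec.nd_od) == (WellRole.EXPOSED, 350.0, 0.2)
        ctrl = pmap.record("H12")
        assert ctrl.role is WellRole.DARK_CONTROL
        assert ctrl.wavelength_nm is None and ctrl.nd_od == 0.0

    def test_roles_case_insensitive(self, tmp_path):
        p = _write(tmp_path / "m.csv", "well,role,wavelength_nm,nd_od\nA01,EXPOSED,300,0\n")
        assert plate_io.read_plate_map(p).record("A01").role is WellRole.EXPOSED

    @pytest.mark.parametrize(
        "body, match",
        [
            ("A01,exposed,350,0\nA01,exposed,360,0\n", "duplicate well"),
            ("A01,zapped,350,0\n", "unknown role"),
            ("A01,exposed,,\n", "lacks wavelength"),
            ("A01,exposed,500,0\n", "outside"),
            ("Z99,exposed,350,0\n", "invalid well label"),
        ],
    )
    def test_rejects_invalid_files(self, tmp_path, body, match):
        p = _write(tmp_path / "bad.csv", "well,role,wavelength_nm,nd_od\n" + body)
        with pytest.raises(FormatError, match=match):
            plate_io.read_plate_map(p)

    def test_round_trip(self, tmp_path):
        pmap = PlateMap(
            [
                WellRecord("A01", WellRole.EXPOSED, 350.0, 0.4),
                WellRecord("B07", WellRole.NO_CELL_CONTROL),
            ],
            plate_id="X",
            replicate_id=2,
        )
        path = tmp_path / "map.csv"
        plate_io.write_plate_map(pmap, path)
        back = plate_io.read_plate_map(path)
        assert back.plate_id == "X" and back.replicate_id == 2
        assert back.entries == pmap.entries


class TestEcisLong:
    HEADER = "time_h,well,frequency_hz,z_ohm,r_ohm,c_farad\n"

    def test_one_trace_per_well_frequency(self, tmp_path):
        body = (
            "0.0,A01,16000,1000,800,1e-8\n"
            "0.183,A01,16000,900,700,1.1e-8\n"
            "0.367,A01,16000,800,600,1.2e-8\n"
            "0.0,A01,4000,2000,1500,2e-8\n"
        )
        traces = plate_io.read_ecis_long(_write(tmp_path / "e.csv", self.HEADER + body))
        assert {(t.well, t.frequency_hz) for t in traces} == {("A01", 16000.0), ("A01", 4000.0)}
        t16 = next(t for t in traces if t.frequency_hz == 16000.0)
        assert t16.n_samples == 3
        assert np.all(np.diff(t16.time_h) > 0)

    def test_rejects_negative_impedance(self, tmp_path):
        p = _write(tmp_path / "e.csv", self.HEADER + "0.0,A01,16000,-5,800,1e-8\n")
        with pytest.raises(FormatError, match="non-positive"):
            plate_io.read_ecis_long(p)

    def test_rejects_duplicate_timestamps(self, tmp_path):
        body = "0.0,A01,16000,1000,800,1e-8\n0.0,A01,16000,990,790,1e-8\n"
        with pytest.raises(FormatError, match="duplicated timestamps"):
            plate_io.read_ecis_long(_write(tmp_path / "e.csv", self.HEADER + body))

    def test_nanofarad_flag_converts_units(self, tmp_path):
        p = _write(tmp_path / "e.csv", self.HEADER + "0.0,A01,16000,1000,800,12.0\n")
        (trace,) = plate_io.read_ecis_long(p, capacitance_unit="nF")
        assert trace.capacitance_f[0] == pytest.approx(12e-9)

    def test_round_trip(self, tmp_path, trace_factory):
        traces = [trace_factory([1000.0, 900.0, 800.0], well="C03")]
        path = tmp_path / "out.csv"
        plate_io.write_ecis_long(traces, path)
        (back,) = plate_io.read_ecis_long(path)
        np.testing.assert_allclose(back.impedance_ohm, traces[0].impedance_ohm)
        np.testing.assert_allclose(back.time_h, traces[0].time_h)


class TestFeatureTable:
    def test_prefix_tagging(self, tmp_path):
        p = _write(
            tmp_path / "f.csv",
            "well,nucleus__ser_spot__Hoechst SER Spot 1px,ros__intensity__DCF mean\nA01,1.0,2.0\n",
        )
        table = plate_io.read_feature_table(p)
        col = "nucleus__ser_spot__Hoechst SER Spot 1px"
        assert table.tags.loc[col, "compartment"] == "nucleus"
        assert table.tags.loc[col, "kernel"] == "ser_spot"
        assert table.n_features == 2

    def test_sidecar_covers_unprefixed_columns(self, tmp_path):
        p = _write(tmp_path / "f.csv", "well,raw feature\nA01,3.5\n")
        side = _write(
            tmp_path / "tags.csv",
            "column,compartment,kernel,name\nraw feature,mitochondria,count,mito count\n",
        )
        table = plate_io.read_feature_table(p, sidecar=side)
        assert table.tags.loc["raw feature", "compartment"] == "mitochondria"

    def test_untaggable_column_errors_with_names(self, tmp_path):
        p = _write(tmp_path / "f.csv", "well,mystery,nucleus__count__n\nA01,1,2\n")
        with pytest.raises(FormatError, match="mystery"):
            plate_io.read_feature_table(p)

    def test_generated_table_has_380_tagged_features(self, tmp_path, paper_profile):
        table, _, _, _ = gen_feature_table(paper_profile, n_features=380, seed=0)
        assert table.n_features == 380
        path = tmp_path / "features.csv"
        plate_io.write_feature_table(table, path)
        back = plate_io.read_feature_table(path)
        assert back.n_features == 380
        assert sorted(back.tags["compartment"].unique()) == sorted(plate_io.COMPARTMENTS)
        np.testing.assert_allclose(back.values.to_numpy(), table.values.to_numpy(), rtol=1e-12)

    def test_select_filters_by_tag(self, paper_profile):
        table, _, _, _ = gen_feature_table(paper_profile, n_features=380, seed=0)
        spot = table.select(kernel="ser_spot")
        assert spot and all("ser_spot" in c for c in spot)
        nuc_spot = table.select(compartment="nucleus", kernel="ser_spot")
        assert set(nuc_spot) < set(spot)


class TestSpectrum:
    def test_reads_uniform_grid(self, tmp_path):
        grid = np.arange(290, 406)
        body = "wavelength_nm,irradiance\n" + "\n".join(f"{w},0.5" for w in grid)
        spec = plate_io.read_spectrum(_write(tmp_path / "s.csv", body))
        assert len(spec.grid_nm) == 116

    def test_rejects_2nm_spacing(self, tmp_path):
        body = "wavelength_nm,irradiance\n290,1\n292,1\n294,1\n"
        with pytest.raises(FormatError, match="1 nm"):
            plate_io.read_spectrum(_write(tmp_path / "s.csv", body))

    def test_result_round_trip_12_digits(self, tmp_path):
        df = pd.DataFrame(
            {
                "wavelength_nm": [290.0, 405.0],
                "efficiency": [1.23456789012345e-3, 9.87654321098765e-7],
                "normalised_efficiency": [1250.000000001, 1.0],
            }
        )
        path = tmp_path / "r.csv"
        plate_io.write_spectrum_csv(df, path)
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["efficiency"], df["efficiency"], rtol=1e-12)
        np.testing.assert_allclose(
            back["normalised_efficiency"], df["normalised_efficiency"], rtol=1e-12
        )

    def test_gzip_by_extension(self, tmp_path):
        body = "well,rfu\nA01,1000\n"
        path = tmp_path / "v.csv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(body)
        plate = plate_io.read_viability_plate(path)
        assert plate.readings["A01"] == 1000.0


class TestViabilityPlate:
    def test_rejects_negative_rfu(self):
        with pytest.raises(FormatError, match="negative RFU"):
            ViabilityPlate("P", {"A01": -1.0})

    def test_round_trip(self, tmp_path):
        plate = ViabilityPlate("P9", {"A01": 123.5, "B02": 456.0})
        path = tmp_path / "v.csv"
        plate_io.write_viability_plate(plate, path)
        back = plate_io.read_viability_plate(path)
        assert back.plate_id == "P9"
        assert back.readings == plate.readings
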