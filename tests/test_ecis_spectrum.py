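import numpy as np
import pytest

from actinospec.ecis_spectrum import build_action_spectrum, time_to_threshold, truncate_at_lamp_off
from actinospec.plate_io import PlateMap, WellRecord, WellRole
from actinospec.synthetic_data import ECIS_WAVELENGTHS, gen_ecis_traces, preset


def _norm_trace(values, well="A01", dt_h=11.0 / 60.0, factory=None):
    return factory(values, well=well, dt_h=dt_h, normalized=True)


class TestTimeToThreshold:
    def test_linear_decay_analytic_crossing(self, trace_factory):
        t = np.arange(0, 100.0001, 11.0 / 60.0)
        tr = trace_factory(1.0 - t / 100.0, normalized=True)
        assert time_to_threshold(tr, "impedance", 0.6) == pytest.approx(40.0, abs=1e-9)

    def test_flat_trace_censored(self, trace_factory):
        tr = trace_factory(np.ones(50), normalized=True)
        assert time_to_threshold(tr) is None

    def test_first_crossing_counts_despite_recovery(self, trace_factory):
        v = np.concatenate([np.linspace(1, 0.5, 20), np.linspace(0.5, 1.0, 20)])
        tr = trace_factory(v, normalized=True)
        t_cross = time_to_threshold(tr)
        assert t_cross is not None and t_cross < 20 * 11.0 / 60.0

    def test_agrees_with_dense_grid_oracle(self, trace_factory):
        rng = np.random.default_rng(7)
        dt = 11.0 / 60.0
        for _ in range(50):
            drops = rng.uniform(0, 0.05, size=80)
            v = 1.0 - np.concatenate([[0.0], np.cumsum(drops)])
            tr = trace_factory(v, normalized=True)
            got = time_to_threshold(tr, "impedance", 0.6)
            t = np.arange(len(v)) * dt
            fine_t = np.linspace(t[0], t[-1], 500001)
            fine_v = np.interp(fine_t, t, v)
            below = fine_v <= 0.6
            oracle = fine_t[np.argmax(below)] if below.any() else None
            if oracle is None:
                assert got is None
            else:
                assert got == pytest.approx(oracle, abs=dt)

    def test_raw_trace_rejected(self, trace_factory):
        with pytest.raises(ValueError, match="normalised"):
            time_to_threshold(trace_factory([1000.0, 500.0]))

    def test_empty_window_rejected(self, trace_factory):
        tr = trace_factory(np.ones(5), normalized=True)
        with pytest.raises(ValueError, match="window"):
            time_to_threshold(tr, window=(5.0, 5.0))

    def test_monotone_consistency(self, trace_factory):
        rng = np.random.default_rng(3)
        upper = 1.0 - np.concatenate([[0.0], np.cumsum(rng.uniform(0, 0.03, 60))])
        lower = upper - rng.uniform(0.0, 0.1, size=upper.shape)
        lower[0] = 1.0
        ta = time_to_threshold(trace_factory(lower, normalized=True))
        tb = time_to_threshold(trace_factory(upper, normalized=True))
        if tb is not None:
            assert ta is not None and ta <= tb


class TestTruncateAtLampOff:
    def test_post_douse_samples_removed(self, trace_factory):
        t72 = trace_factory(np.linspace(1, 0.2, 72 * 6), normalized=True, dt_h=1 / 6)
        out = truncate_at_lamp_off(t72, 68.0)
        assert out.time_h[-1] <= 68.0

    def test_short_trace_unchanged(self, trace_factory):
        t60 = trace_factory(np.linspace(1, 0.8, 60), normalized=True)
        out = truncate_at_lamp_off(t60, 68.0)
        assert out.n_samples == t60.n_samples

    def test_crossing_before_cutoff_still_detected(self, trace_factory):
        # trace recovers above threshold after lamp-off; windowing must not hide
        # the earlier crossing
        t = np.arange(0, 72, 11.0 / 60.0)
        v = np.where(t < 68.0, 1.0 - t / 80.0, 1.2)
        tr = trace_factory(v, normalized=True)
        out = truncate_at_lamp_off(tr, 68.0)
        assert time_to_threshold(out) == pytest.approx(0.4 * 80.0, abs=11.0 / 60.0)


class TestBuildActionSpectrum:
    def test_mean_of_reciprocal_doses(self, paper_profile, trace_factory):
        t = np.arange(0, 72.0001, 11.0 / 60.0)
        entries = [
            WellRecord("A01", WellRole.NO_CELL_CONTROL),
            WellRecord("A02", WellRole.DARK_CONTROL),
            WellRecord("B01", WellRole.EXPOSED, 350.0, 0.0),
            WellRecord("B02", WellRole.EXPOSED, 350.0, 0.0),
            WellRecord("C01", WellRole.EXPOSED, 400.0, 0.0),
        ]
        pmap = PlateMap(entries)

        def raw(g):
            return trace_factory(300.0 + 0.95 * g * (1800.0 - 300.0))

        traces = [
            trace_factory(np.full_like(t, 300.0), well="A01", dt_h=11 / 60),
            trace_factory(np.full_like(t, 1800.0), well="A02", dt_h=11 / 60),
        ]
        for well, t_cross in (("B01", 20.0), ("B02", 40.0), ("C01", 50.0)):
            g = np.maximum(0.01, 1.0 - 0.4 * t / t_cross)
            tr = trace_factory(300.0 + 0.95 * g * 1500.0, well=well, dt_h=11 / 60)
            traces.append(tr)
        irr = {"B01": 2.0, "B02": 2.0, "C01": 1.0}
        spec = build_action_spectrum(traces, pmap, irr, reference_nm=400.0)
        d20, d40 = 2.0 * 20 * 3600, 2.0 * 40 * 3600
        assert spec.loc[350.0, "efficiency"] == pytest.approx(
            (1 / d20 + 1 / d40) / 2, rel=0.01
        )

    def test_halving_irradiance_doubles_efficiency(self, trace_factory):
        t = np.arange(0, 72.0001, 11.0 / 60.0)
        g = np.maximum(0.01, 1.0 - 0.4 * t / 30.0)
        entries = [
            WellRecord("A01", WellRole.NO_CELL_CONTROL),
            WellRecord("A02", WellRole.DARK_CONTROL),
            WellRecord("B01", WellRole.EXPOSED, 350.0, 0.0),
            WellRecord("B02", WellRole.EXPOSED, 400.0, 0.0),
        ]
        pmap = PlateMap(entries)
        traces = [
            trace_factory(np.full_like(t, 300.0), well="A01", dt_h=11 / 60),
            trace_factory(np.full_like(t, 1800.0), well="A02", dt_h=11 / 60),
            trace_factory(300.0 + 0.95 * g * 1500.0, well="B01", dt_h=11 / 60),
            trace_factory(300.0 + 0.95 * g * 1500.0, well="B02", dt_h=11 / 60),
        ]
        spec = build_action_spectrum(traces, pmap, {"B01": 1.0, "B02": 2.0}, reference_nm=400.0)
        assert spec.loc[350.0, "normalised_efficiency"] == pytest.approx(2.0, rel=1e-6)

    def test_noiseless_generator_inversion_within_one_interval(self, paper_profile):
        traces, pmap, irr = gen_ecis_traces(
            paper_profile, wells_per_wavelength=1, noise_sd=0.0, seed=2
        )
        spec = build_action_spectrum(traces, pmap, irr)
        for wl in ECIS_WAVELENGTHS:
            planted = paper_profile.ecis_crossing_h(wl)
            got = spec.loc[wl, "mean_time_to_action_h"]
            assert got == pytest.approx(planted, abs=11.0 / 60.0), wl

    def test_noisy_recovery_within_1p5_fold(self, paper_profile):
        traces, pmap, irr = gen_ecis_traces(
            paper_profile, wells_per_wavelength=4, noise_sd=0.02, seed=4
        )
        spec = build_action_spectrum(traces, pmap, irr)
        for wl in ECIS_WAVELENGTHS:
            planted = paper_profile.ecis_efficiency[wl]
            got = spec.loc[wl, "normalised_efficiency"]
            assert planted / 1.5 <= got <= planted * 1.5, (wl, got, planted)

    def test_censored_wells_counted_not_averaged(self, paper_profile, trace_factory):
        t = np.arange(0, 72.0001, 11.0 / 60.0)
        entries = [
            WellRecord("A01", WellRole.NO_CELL_CONTROL),
            WellRecord("A02", WellRole.DARK_CONTROL),
            WellRecord("B01", WellRole.EXPOSED, 350.0, 0.0),
            WellRecord("B02", WellRole.EXPOSED, 350.0, 0.0),
            WellRecord("C01", WellRole.EXPOSED, 400.0, 0.0),
        ]
        pmap = PlateMap(entries)
        g_cross = np.maximum(0.01, 1.0 - 0.4 * t / 30.0)
        traces = [
            trace_factory(np.full_like(t, 300.0), well="A01", dt_h=11 / 60),
            trace_factory(np.full_like(t, 1800.0), well="A02", dt_h=11 / 60),
            trace_factory(300.0 + 0.95 * g_cross * 1500.0, well="B01", dt_h=11 / 60),
            trace_factory(np.full_like(t, 1700.0), well="B02", dt_h=11 / 60),  # never crosses
            trace_factory(300.0 + 0.95 * g_cross * 1500.0, well="C01", dt_h=11 / 60),
        ]
        spec = build_action_spectrum(traces, pmap, {"B01": 1.0, "B02": 1.0, "C01": 1.0})
        assert spec.loc[350.0, "n_censored"] == 1
        assert spec.loc[350.0, "n_wells"] == 1
        # efficiency equals the uncensored well's, not dragged down by the censored one
        assert spec.loc[350.0, "normalised_efficiency"] == pytest.approx(1.0, rel=1e-6)


class TestTwoSidedThreshold:
    def test_upward_crossing_detected_for_rising_parameter(self, trace_factory):
        t = np.arange(0, 30, 11.0 / 60.0)
        v = 1.0 + t / 20.0  # rises through 1/0.6 at t = 20*(1/0.6 - 1)
        tr = trace_factory(v, normalized=True)
        assert time_to_threshold(tr, direction="down") is None
        up = time_to_threshold(tr, direction="up")
        assert up == pytest.approx(20.0 * (1.0 / 0.6 - 1.0), abs=11.0 / 60.0)
        assert time_to_threshold(tr, direction="both") == pytest.approx(up)

    def test_both_takes_earliest_crossing(self, trace_factory):
        t = np.arange(0, 30, 11.0 / 60.0)
        v = 1.0 - t / 40.0
        tr = trace_factory(v, normalized=True)
        down = time_to_threshold(tr, direction="down")
        assert time_to_threshold(tr, direction="both") == pytest.approx(down)

    def test_invalid_direction_rejected(self, trace_factory):
        tr = trace_factory(np.ones(5), normalized=True)
        with pytest.raises(ValueError, match="direction"):
            time_to_threshold(tr, direction="sideways")
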