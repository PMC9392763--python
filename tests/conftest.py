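import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from actinospec.plate_io import EcisTrace, PlateMap, ViabilityPlate, WellRecord, WellRole
from actinospec.synthetic_data import preset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_profile():
    return preset("paper-profile")


@pytest.fixture
def small_map():
    """Minimal plate: two exposed conditions plus the three control roles."""
    return PlateMap(
        [
            WellRecord("A01", WellRole.LYSED_CONTROL),
            WellRecord("A02", WellRole.LYSED_CONTROL),
            WellRecord("A03", WellRole.DARK_CONTROL),
            WellRecord("A04", WellRole.DARK_CONTROL),
            WellRecord("B01", WellRole.EXPOSED, 350.0, 0.0),
            WellRecord("B02", WellRole.EXPOSED, 350.0, 0.2),
            WellRecord("B03", WellRole.EXPOSED, 380.0, 0.0),
        ],
        plate_id="P1",
        replicate_id=1,
    )


@pytest.fixture
def small_viability_plate():
    return ViabilityPlate(
        "P1",
        {
            "A01": 5200.0,
            "A02": 4800.0,
            "A03": 44000.0,
            "A04": 46000.0,
            "B01": 25000.0,
            "B02": 15000.0,
            "B03": 45000.0,
        },
    )


def make_trace(values, well="A01", dt_h=11.0 / 60.0, normalized=False, scale=1.0):
    """Build an EcisTrace whose three parameters all follow ``values``."""
    v = np.asarray(values, dtype=float) * scale
    t = np.arange(len(v)) * dt_h
    return EcisTrace(
        well=well,
        frequency_hz=16000.0,
        time_h=t,
        impedance_ohm=v,
        resistance_ohm=v,
        capacitance_f=v * 1e-9 if not normalized else v,
        normalized=normalized,
    )


@pytest.fixture
def trace_factory():
    return make_trace
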