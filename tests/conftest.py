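import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cervinet.kinematics import AngleTrace, MovementSummary
from cervinet.nfhas import MOVEMENTS
from cervinet.preprocessing import AssessmentRecord


@pytest.fixture
def sine_trace() -> AngleTrace:
    """Pure sinusoid: amplitude 30 deg, period 3 s, 45 s at 100 Hz."""
    t = np.arange(0.0, 45.0, 0.01)
    return AngleTrace(movement="F", time=t, angle=30.0 * np.sin(2.0 * np.pi * t / 3.0))


def make_record(
    patient_id: str = "P1",
    time_point: str = "baseline",
    rom_normalized: float = 80.0,
    cv: float = 5.0,
    speed: float = 60.0,
    **overrides,
) -> AssessmentRecord:
    movements = {
        m: MovementSummary(
            movement=m,
            mean_rom=overrides.get(f"rom_{m}", rom_normalized / 2),
            rom_normalized=overrides.get(f"romn_{m}", rom_normalized),
            cv=overrides.get(f"cv_{m}", cv),
            speed_to_peak=overrides.get(f"speed_{m}", speed),
            n_repetitions=12,
        )
        for m in MOVEMENTS
    }
    return AssessmentRecord(
        patient_id=patient_id,
        time_point=time_point,
        movements=movements,
        age=40.0,
        sex="F",
        height=1.68,
        mass=70.0,
    )


@pytest.fixture
def record_factory():
    return make_record
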