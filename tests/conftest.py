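import numpy as np
import pytest

from srtmkit.cohort import KineticTruth, simulate_reference_tac, simulate_target_tac
from srtmkit.kinetics import TimeActivityCurve, frame_average
from srtmkit.schedule import FrameSchedule


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def ref_fine():
    """Default noise-free cerebellum-like reference curve on the fine grid."""
    return simulate_reference_tac()


@pytest.fixture(scope="session")
def ref_tac(schedule, ref_fine) -> TimeActivityCurve:
    t, y = ref_fine
    return TimeActivityCurve(schedule, frame_average(t, y, schedule), "cerebellum")


@pytest.fixture(scope="session")
def striatal_tac(schedule, ref_fine) -> TimeActivityCurve:
    """Noise-free striatum-like TAC: R1=1, k2=0.3/min, BP=2.5."""
    truth = KineticTruth(r1=1.0, k2=0.3, bp_nd=2.5, region="striatum")
    return simulate_target_tac(truth, ref_fine, schedule, noise_scale=0.0)
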