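import numpy as np
import pytest

from hrvreact.core import RRSeries
from hrvreact.schedule import build_default_schedule
from hrvreact.simulate import (
    AutonomicProfile,
    SimulationConfig,
    build_profile,
    generate_rr_trajectory,
    synthesize_ecg,
)

PHASES = ("relax1", "stress1", "relax2", "stress2", "relax3")


@pytest.fixture(scope="session")
def schedule():
    return build_default_schedule()


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig()


def flat_profile(hr: float = 60.0, short: float = 0.0, overall: float = 0.0):
    return AutonomicProfile(
        baseline_hr_bpm=hr,
        phase_hr_bpm={p: hr for p in PHASES},
        attenuation=1.0,
        short_term_amp_s=short,
        overall_amp_s=overall,
    )


@pytest.fixture(scope="session")
def clean_rr(schedule):
    """A realistic noise-free-profile RR series over the protocol."""
    cfg = SimulationConfig()
    prof = build_profile("FM", 2, cfg, np.random.default_rng(3))
    return generate_rr_trajectory(prof, schedule, 3)


@pytest.fixture(scope="session")
def clean_ecg(schedule, clean_rr):
    return synthesize_ecg(clean_rr, 1000.0, duration_s=schedule.total_duration_s)


def rr_from_intervals(intervals, start: float = 0.0, flags=None) -> RRSeries:
    ends = start + np.cumsum(intervals)
    return RRSeries(np.asarray(intervals, dtype=float), ends, flags)
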