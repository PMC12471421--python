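import numpy as np
import pytest

from swinescore import (DiurnalStats, SimulationConfig, derive_news2_table,
                        derive_sirs_table, reference)
from swinescore.scores import VitalsSnapshot

#: healthy values sitting squarely inside every normal band
NORMAL = {
    "day": dict(hr=100.0, rr=22.0, temp=38.5, sbp=140.0, map=100.0),
    "night": dict(hr=92.0, rr=16.0, temp=38.8, sbp=132.0, map=100.0),
    "shared": dict(wbc=19.1, platelets=350.0, creatinine=1.0, bilirubin=0.4,
                   pf_ratio=450.0, snort=11.0, spo2=98.0),
}


def make_snapshot(phase="day", **overrides) -> VitalsSnapshot:
    values = dict(NORMAL[phase], **NORMAL["shared"])
    values.update(overrides)
    return VitalsSnapshot(animal_id="test", time_h=8.0, phase=phase, **values)


@pytest.fixture(scope="session")
def printed_stats() -> DiurnalStats:
    return DiurnalStats.from_summary(reference.BASELINE_STATS)


@pytest.fixture(scope="session")
def sirs_table(printed_stats):
    return derive_sirs_table(printed_stats)


@pytest.fixture(scope="session")
def news2_bands(printed_stats):
    return derive_news2_table(printed_stats)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240108)


@pytest.fixture
def small_config() -> SimulationConfig:
    """A cheap cohort: coarse telemetry, few animals."""
    return SimulationConfig(n_control=2, n_pat=3, telemetry_step_min=30.0, seed=7)
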