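import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from sacmod.oculosim import (
    CohortConfig,
    GroupLatencyModel,
    SubjectParams,
    simulate_trial,
)


@pytest.fixture
def noiseless_subject():
    """A control subject with a fixed 200 ms latency and no variability."""
    return SubjectParams(
        subject_id="S1", group="control",
        latency_mean_ms={"color": 200.0, "landolt": 200.0},
        within_sd_ms=0.0,
        rt_mean_ms={"color": 800.0, "landolt": 900.0},
        rt_within_sd_ms=100.0,
        accuracy={"color": 1.0, "landolt": 1.0})


@pytest.fixture
def noiseless_trial(noiseless_subject):
    """One noiseless rightward color trial (trace, event, truth)."""
    return simulate_trial(noiseless_subject, "color", "right",
                          noise_sd_deg=0.0, seed=1)


@pytest.fixture
def small_cohort_config():
    """A fast 3-group cohort: 4 subjects per group, 16 trials each."""
    return CohortConfig(group_sizes={"patient": 4, "control": 4, "relative": 4},
                        n_trials=16, n_blocks=1, seed=9)


@pytest.fixture
def separable_features():
    """Two widely separated clusters: patients slow, comparison fast."""
    rng = np.random.default_rng(5)
    rows = []
    for i in range(15):
        rows.append(dict(subject_id=f"P{i}", group="patient",
                         sl_landolt=500 + rng.normal(0, 5),
                         sl_color=500 + rng.normal(0, 5)))
    for g, k in (("control", 24), ("relative", 10)):
        for i in range(k):
            rows.append(dict(subject_id=f"{g[0].upper()}{i}", group=g,
                             sl_landolt=150 + rng.normal(0, 5),
                             sl_color=150 + rng.normal(0, 5)))
    return pd.DataFrame(rows)


@pytest.fixture
def chance_features():
    """Features with no group signal at all (chance-level classification)."""
    rng = np.random.default_rng(42)
    rows = []
    for g, k in (("patient", 13), ("control", 24), ("relative", 10)):
        for i in range(k):
            rows.append(dict(subject_id=f"{g}{i}", group=g,
                             sl_color=250 + rng.normal(0, 50),
                             sl_landolt=250 + rng.normal(0, 50)))
    return pd.DataFrame(rows)
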