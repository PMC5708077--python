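from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnvarray.core import LogRatioProfile, ProbeMap
from cnvarray.synthetic_cohort import make_probe_map


@pytest.fixture
def small_map() -> ProbeMap:
    """One 100-probe chromosome at 1 kb spacing."""
    return make_probe_map({"chrA": 100_000}, 1_000)


@pytest.fixture
def profile_factory(small_map):
    def build(ratios, sample_id="s1", group="case", probe_map=None):
        return LogRatioProfile(
            sample_id, group, probe_map or small_map, np.asarray(ratios, dtype=float)
        )

    return build


@pytest.fixture
def sheet():
    return pd.DataFrame(
        {
            "sample_id": ["case_001", "case_002", "case_003", "control_001", "control_002"],
            "group": ["case", "case", "case", "control", "control"],
            "sex": ["M", "F", "M", "F", "M"],
        }
    )


@pytest.fixture(scope="session")
def demo_result():
    """Full demo two-stage run, shared across tests (expensive)."""
    from cnvarray.demo import run_demo_two_stage

    return run_demo_two_stage(seed=1)
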