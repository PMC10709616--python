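import numpy as np
import pandas as pd
import pytest

from thoughtspace import synth


@pytest.fixture(scope="session")
def gradients():
    return synth.make_gradients(400, 5, seed=1)


@pytest.fixture(scope="session")
def small_gradients():
    return synth.make_gradients(150, 5, seed=3)


@pytest.fixture(scope="session")
def truth():
    return synth.default_truth(seed=1)


@pytest.fixture()
def scanning_config():
    """The scanning-session cohort: 62 participants, 3 runs x 8 probes,
    4 participants missing one run."""
    return synth.SimulationConfig(n_participants=62, n_runs=3, n_missing_run=4, seed=1)


@pytest.fixture(scope="session")
def paired_data():
    """Balanced 2-level within-participant data with a participant intercept."""
    rng = np.random.default_rng(42)
    n = 57
    subj = np.repeat([f"p{i:02d}" for i in range(n)], 2)
    cond = np.tile(["vigilance", "target"], n)
    y = (
        np.repeat(rng.normal(0, 0.5, n), 2)
        + 0.2 * (cond == "vigilance")
        + rng.normal(0, 0.3, 2 * n)
    )
    return pd.DataFrame({"participant": subj, "map": cond, "y": y})
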