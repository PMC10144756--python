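import numpy as np
import pytest

from postlrs import EyeRecord, SimulationConfig, simulate_cohort


def make_eye(al, k, a_const=118.4, p_iol=20.0, se_post=0.0,
             model="X", eye_id="e", source="clinic"):
    return EyeRecord(eye_id, al, k, a_const, model, p_iol, se_post, source)


@pytest.fixture(scope="session")
def biometry_grid():
    """Deterministic 200-eye (AL, K) grid spanning the post-LRS domain."""
    al = np.linspace(23.8, 34.0, 20)
    k = np.linspace(32.0, 43.5, 10)
    return [(a, kk) for a in al for kk in k]


@pytest.fixture(scope="session")
def seeded_cohort():
    """One noisy 132-eye cohort under the default study conditions."""
    cfg = SimulationConfig(n_eyes=132, seed=20230415)
    return simulate_cohort(cfg)
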