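import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "calfsid",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("calfsid")


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-calf synthetic cohort shared by the faster integration tests."""
    from calfsid.cohort import default_cohort_spec, generate_cohort

    return generate_cohort(default_cohort_spec(n=600, seed=42))


@pytest.fixture()
def planted_tree_frame():
    """Noiseless two-rule mortality data: die iff ph < 6.85 or cns flag."""
    rng = np.random.default_rng(7)
    n = 2000
    ph = rng.normal(7.18, 0.21, n)
    cns = (rng.random(n) < 0.06).astype(int)
    df = pd.DataFrame(
        {
            "ph": ph,
            "cns": cns,
            "noise_a": rng.normal(0, 1, n),
            "noise_b": rng.normal(5, 2, n),
            "died": ((ph < 6.85) | (cns == 1)).astype(int),
        }
    )
    return df
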