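import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from irindices import default_config, simulate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def random_cohort_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Unstructured random cohort over wide physiologic ranges.

    Independent of the calibrated generator on purpose: oracle-equivalence
    tests must not inherit its distributional structure.
    """
    return pd.DataFrame(
        {
            "id": [f"R{i}" for i in range(n)],
            "sex": rng.choice(["M", "F"], size=n),
            "age": rng.uniform(18, 70, n),
            "height_cm": rng.uniform(140, 190, n),
            "weight_kg": rng.uniform(35, 110, n),
            "waist_cm": rng.uniform(55, 130, n),
            "hip_cm": rng.uniform(70, 140, n),
            "sbp_mmhg": rng.uniform(90, 180, n),
            "dbp_mmhg": rng.uniform(50, 110, n),
            "fpg_mgdl": rng.uniform(60, 200, n),
            "insulin_uiu_ml": rng.uniform(0.5, 40, n),
            "tc_mgdl": rng.uniform(100, 300, n),
            "hdl_mgdl": rng.uniform(20, 90, n),
            "tg_mgdl": rng.uniform(40, 450, n),
            "ldl_mgdl": np.nan,
        }
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized cohort (n=192) with its planted labels."""
    return simulate_cohort(default_config(seed=20230111))


@pytest.fixture(scope="session")
def large_cohort():
    """Large-n cohort for calibration checks (single shared draw)."""
    return simulate_cohort(default_config(seed=7, n=20_000))
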