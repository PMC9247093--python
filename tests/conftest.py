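import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def small_cohort():
    """Two-sex toy cohort with analytically known structure."""
    rng = np.random.default_rng(42)
    n = 200
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    age = rng.uniform(45, 80, n)
    bmi = rng.normal(27, 4, n)
    height = np.where(sex == "female", rng.normal(163, 6, n), rng.normal(176, 7, n))
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "height": height,
            "vat": np.abs(rng.normal(4, 1.5, n)) + 0.2,
            "asat": np.abs(rng.normal(7, 2, n)) + 0.2,
            "gfat": np.abs(rng.normal(10, 2, n)) + 0.2,
        }
    )
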