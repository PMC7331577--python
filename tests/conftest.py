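import numpy as np
import pandas as pd
import pytest

import metabosurv as ms


@pytest.fixture(scope="session")
def default_cohort():
    """One medium synthetic cohort shared by read-only tests."""
    cohort, record = ms.generate_cohort(ms.GeneratorConfig(n_patients=475, seed=42))
    return cohort, record


@pytest.fixture()
def small_survival_frame():
    """Tiny deterministic survival frame for hand-checkable fits."""
    rng = np.random.default_rng(7)
    n = 60
    x = rng.normal(size=n)
    t = rng.exponential(1 / np.exp(0.5 * x))
    c = rng.uniform(0.2, 2.0, n)
    return pd.DataFrame(
        {
            "time_years": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "x": x,
            "z": rng.normal(size=n),
        }
    )
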