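import numpy as np
import pandas as pd
import pytest

from cadcea import schema
from cadcea.impute import MICEImputer
from cadcea.synth import CohortSpec, apply_mar_ltfu, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 250/250 cohort with MAR dropout applied."""
    spec = CohortSpec(n_control=250, n_intervention=250, seed=11)
    return apply_mar_ltfu(generate_cohort(spec))


@pytest.fixture(scope="session")
def small_wide(small_cohort):
    return schema.to_wide(small_cohort.records)


@pytest.fixture(scope="session")
def imputed_small(small_wide):
    """Three completed datasets from a short chained-equations run."""
    return MICEImputer(m=3, iterations=3, random_state=11).fit(small_wide)


@pytest.fixture(scope="session")
def imputed_small_long(imputed_small):
    return [schema.to_long(d) for d in imputed_small.datasets_]


@pytest.fixture()
def published_ledger():
    """Per-arm cost items as published: programme rows plus participant/
    community-worker out-of-pocket and productivity subtotals (USD,
    already inflation-adjusted)."""
    rows = [
        ("CAW salary", "health_system", "CAD", "programme", 235_260.00),
        ("Training (CAD)", "health_system", "CAD", "programme", 6_007.37),
        ("CAW meetings and communication", "health_system", "CAD", "programme", 9_055.03),
        ("Training (MMD)", "health_system", "MMD", "programme", 4_733.30),
        ("OOPE participants+caregivers (MMD)", "societal", "MMD", "participant", 58_764.57),
        ("OOPE participants+caregivers (CAD)", "societal", "CAD", "participant", 51_008.84),
        ("OOPE CAW (CAD)", "societal", "CAD", "caw", 135_891.18),
        ("Productivity participants (MMD)", "societal", "MMD", "participant", 21_910.09),
        ("Productivity participants (CAD)", "societal", "CAD", "participant", 18_007.79),
        ("Productivity CAW (CAD)", "societal", "CAD", "caw", 85_991.17),
    ]
    return pd.DataFrame(rows, columns=["label", "perspective", "arm", "payer", "amount"]).assign(
        currency="USD", cpi_source=1.0, cpi_target=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
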