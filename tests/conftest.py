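import numpy as np
import pandas as pd
import pytest

from demosae.ages import AGE_GROUPS
from demosae.synthetic import (
    GeneratorConfig,
    generate_auxiliaries,
    generate_truth,
    simulate_microdata,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Small study fixture: 10 districts x 400 women."""
    return GeneratorConfig(n_districts=10, n_women=400, n_psu=10, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    truth = generate_truth(small_config)
    women, children = simulate_microdata(truth, small_config)
    aux = generate_auxiliaries(truth, small_config)
    return truth, women, children, aux


def brute_force_exposure(
    women: pd.DataFrame, children: pd.DataFrame, window_months: int = 36
):
    """Independent per-woman month loop computing the event/exposure
    table — the oracle for the vectorized tabulator."""
    events = {}
    exposure = {}
    for _, w in women.iterrows():
        for k in range(1, window_months + 1):
            age_m = w["interview_cmc"] - k - w["birth_cmc"]
            years = age_m // 12
            if 15 <= years <= 49:
                g = AGE_GROUPS[(years - 15) // 5]
                key = (w["district_id"], g)
                exposure[key] = exposure.get(key, 0.0) + w["weight"] / 12.0
    mothers = women.set_index("woman_id")
    for _, c in children.iterrows():
        m = mothers.loc[c["woman_id"]]
        if (
            m["interview_cmc"] - window_months
            <= c["child_birth_cmc"]
            <= m["interview_cmc"] - 1
        ):
            years = (c["child_birth_cmc"] - m["birth_cmc"]) // 12
            if 15 <= years <= 49:
                g = AGE_GROUPS[(years - 15) // 5]
                key = (m["district_id"], g)
                events[key] = events.get(key, 0.0) + m["weight"]
    return events, exposure


def make_cells(events, exposure) -> pd.DataFrame:
    """7-row fertility cell table from plain sequences."""
    return pd.DataFrame(
        {
            "age_group": list(AGE_GROUPS),
            "events": np.asarray(events, dtype=float),
            "exposure": np.asarray(exposure, dtype=float),
        }
    )
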