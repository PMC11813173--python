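import warnings

import numpy as np
import pandas as pd
import pytest

import dscorekit as dk


@pytest.fixture(scope="session")
def dutch_reference() -> dk.ReferenceTable:
    return dk.ReferenceTable.dutch()


@pytest.fixture(scope="session")
def worked_example_bank() -> dk.ItemBank:
    we = dk.load_fixture("worked_example")
    return dk.ItemBank(
        [dk.Item(code=r.item, label=r.label, difficulty_d=r.delta) for r in we.itertuples()]
    )


@pytest.fixture(scope="session")
def synthetic_bank() -> dk.ItemBank:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dk.synthetic_itembank()


@pytest.fixture(scope="session")
def small_cohort(synthetic_bank):
    """400-child nine-visit cohort with truth tables (session-cached)."""
    design = dk.CohortDesign.smocc_like(synthetic_bank, n_children=400)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        responses, truth = dk.simulate_cohort(
            design, dk.GrowthModel(), synthetic_bank, seed=2024
        )
    return responses, truth


def dense_response_set(
    n_children: int, difficulties: np.ndarray, seed: int, ability_sd: float = 2.0,
    ability_mean: float = 0.0,
) -> tuple[dk.ResponseSet, np.ndarray]:
    """Single-visit design where every child answers every item."""
    rng = np.random.default_rng(seed)
    k = len(difficulties)
    beta = rng.normal(ability_mean, ability_sd, n_children)
    x = dk.simulate_responses(beta[:, None], np.asarray(difficulties)[None, :], rng)
    df = pd.DataFrame(
        {
            "child_id": np.repeat([f"c{i:04d}" for i in range(n_children)], k),
            "wave": "w1",
            "age_days": 365.0,
            "item": np.tile([f"i{j:02d}" for j in range(k)], n_children),
            "score": x.ravel(),
        }
    )
    return dk.ResponseSet(df), beta
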