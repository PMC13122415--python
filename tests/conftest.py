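import numpy as np
import pandas as pd
import pytest

from intervalconsensus.model import (
    ConsensusParam,
    Hyperparams,
    sample_items,
    sample_persons,
    simulate_responses,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A small fully-crossed simulated dataset with known true parameters."""
    rng = np.random.default_rng(42)
    hp = Hyperparams()
    J, N = 6, 12
    T = ConsensusParam(rng.normal(0, 0.5, J), rng.normal(-0.5, 0.5, J))
    persons = sample_persons(N, hp, rng)
    items = sample_items(J, hp, rng)
    data = simulate_responses(T, persons, items, rng=rng)
    return data, {"T": T, "persons": persons, "items": items, "hp": hp}


@pytest.fixture()
def response_csv(tmp_path):
    """A tiny well-formed response CSV on disk."""
    frame = pd.DataFrame(
        {
            "respondent_id": ["r1", "r1", "r2", "r2", "r3", "r3"],
            "item_id": ["a", "b", "a", "b", "a", "b"],
            "lower": [0.2, 0.1, 0.25, 0.15, 0.3, 0.05],
            "upper": [0.5, 0.4, 0.55, 0.35, 0.6, 0.45],
        }
    )
    path = tmp_path / "responses.csv"
    frame.to_csv(path, index=False)
    return path, frame
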