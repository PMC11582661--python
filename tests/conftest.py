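import numpy as np
import pandas as pd
import pytest

import panelmsm as pm


@pytest.fixture(scope="session")
def structure():
    return pm.default_transition_structure()


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated cohort shared across tests (fixed seed)."""
    cfg = pm.SimulationConfig(n_individuals=300, horizon=1800, seed=42)
    datasets, truth, histories = pm.generate_dataset(cfg)
    return cfg, datasets, truth, histories


def two_state_params(rate=0.1, pair=(1, 3)):
    """A degenerate structure with a single permitted transition."""
    structure = pm.TransitionStructure((pair,))
    return pm.ModelParameters(structure, {pair: float(np.log(rate))})


def records_frame(rows):
    """Build an observation DataFrame from (id, t, state) triples."""
    df = pd.DataFrame(rows, columns=["individual_id", "time_days", "state"])
    df["gender"] = "Female"
    df["slum_area"] = "Korogocho"
    df["ethnicity"] = "Kamba"
    df["area_of_birth"] = "Nairobi non-slum"
    df["age"] = 20.0
    return df
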