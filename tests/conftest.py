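import numpy as np
import pandas as pd
import pytest

import sapmodels as sm


@pytest.fixture(scope="session")
def cohort500():
    """Standard synthetic study conditions: 500 decedents, 12-item panel."""
    config = sm.default_config(n_patients=500, n_items=12, seed=7)
    patients, observations = sm.generate_cohort(config)
    return config, patients, observations


@pytest.fixture(scope="session")
def assembled500(cohort500):
    config, patients, observations = cohort500
    panel = sm.filter_items(observations)
    samples = sm.assemble_time_points(
        sm.filter_to_panel(observations, panel), patients)
    train_ids, test_ids = sm.split_patients(patients, 0.5, seed=7)
    train = samples[samples["patient_id"].isin(train_ids)].reset_index(drop=True)
    test = samples[samples["patient_id"].isin(test_ids)].reset_index(drop=True)
    return panel, train, test


@pytest.fixture(scope="session")
def sweep8(assembled500):
    """Exhaustive 3-item sweep over an 8-item subpanel (56 x 6 models)."""
    panel, train, test = assembled500
    nulls = [i for i in panel.retained_items if i not in ("ALB", "LDH", "NEU")]
    items = sorted(["ALB", "LDH", "NEU"] + nulls[:5])
    results = sm.search_all(train, test, items, k=3, seed=7)
    return items, train, test, results
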