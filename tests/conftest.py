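import numpy as np
import pytest

import ordlink as o


@pytest.fixture(scope="session")
def ref_amounts() -> o.ParameterSet:
    return o.load_reference_parameters("amounts")


@pytest.fixture(scope="session")
def ref_odds() -> o.ParameterSet:
    return o.load_reference_parameters("odds")


@pytest.fixture(scope="session")
def small_linked_study(ref_odds):
    """8-subject linked-variant study simulated at the reference estimates."""
    config = o.StudyConfig(seed=202, n_subjects=8, variant="linked")
    dataset, truth = o.simulate_study(config, ref_odds)
    return config, dataset, truth


@pytest.fixture(scope="session")
def small_amounts_study(ref_amounts):
    """6-subject amounts-variant study simulated at the reference estimates."""
    config = o.StudyConfig(seed=404, n_subjects=6, variant="amounts")
    dataset, truth = o.simulate_study(config, ref_amounts)
    return config, dataset, truth


def subject_records(dataset, subject_id, endpoints=None):
    return [r for r in dataset.records
            if r.subject_id == subject_id
            and (endpoints is None or r.endpoint in endpoints)]
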