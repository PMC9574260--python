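import numpy as np
import pytest

from preflook.design import TrialSpec
from preflook.preprocess import preprocess_cohort
from preflook.simulate import generate_cohort


@pytest.fixture(scope="session")
def ds_cohort():
    """21-subject DS-like cohort: CV anticipation only, +200 ms onset shift."""
    trials, design = generate_cohort(21, "DS", seed=424242)
    return trials, design


@pytest.fixture(scope="session")
def ds_bins(ds_cohort):
    trials, design = ds_cohort
    return preprocess_cohort(trials, design)


@pytest.fixture(scope="session")
def td_bins_small():
    """8-subject TD-like cohort, enough for model-structure tests."""
    trials, design = generate_cohort(8, "TD", seed=77)
    return preprocess_cohort(trials, design)


@pytest.fixture
def spec_left():
    return TrialSpec(
        participant_id="S1", trial_index=1, condition="CV", item_id=1,
        target_side="left", order_id=1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
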