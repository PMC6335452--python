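import numpy as np
import pandas as pd
import pytest

from precom.cohort import simulate_cohort
from precom.fitting import fit_cohort


@pytest.fixture(scope="session")
def mm_cohort():
    """Small MM-generated cohort (both tasks) shared across test modules."""
    return simulate_cohort(8, seed=101, generative_model="mm")


@pytest.fixture(scope="session")
def mm_cohort_fits(mm_cohort):
    return fit_cohort(mm_cohort.records, mm_cohort.true_params, n_starts=6, seed=7)


@pytest.fixture()
def tiny_trials():
    """Hand-written 10-trial single-subject fixture with known outcomes."""
    rows = []
    costs = [2, 4, 6, 2, 4, 6, 2, 4, 6, 2]
    types = ["standard"] * 5 + ["precommitment"] * 5
    precommit = ["", "", "", "", "", "yes", "no", "no", "yes", "no"]
    choice = ["LR", "LR", "SR", "LR", "SR", "LR", "LR", "SR", "LR", "LR"]
    opt_out = [False, True, False, False, False, False, False, False, False, False]
    achieved = [True, False, False, True, False, True, True, False, True, True]
    for i in range(10):
        rows.append(
            {
                "subject_id": "T000",
                "task": "effort",
                "trial_index": i,
                "trial_type": types[i],
                "cost_level": float(costs[i]),
                "precommit": precommit[i],
                "choice": choice[i],
                "opt_out": opt_out[i],
                "achieved_LR": achieved[i],
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
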