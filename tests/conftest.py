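import numpy as np
import pytest

from banditmeta.synthetic_experiment import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def exp1_cohort():
    """Small ideal-observer cohort with the rating-heavy design."""
    return generate_cohort(
        CohortSpec(n_subjects=8, design="exp1", master_seed=101)
    )


@pytest.fixture(scope="session")
def exp2_cohort():
    """Small ideal-observer cohort with the choice-heavy design."""
    return generate_cohort(
        CohortSpec(n_subjects=8, design="exp2", master_seed=202)
    )


@pytest.fixture(scope="session")
def rl_cohort():
    """Delta-rule cohort (surprise-sensitive confidence), rating-heavy."""
    return generate_cohort(
        CohortSpec(
            n_subjects=8, design="exp1", master_seed=303,
            model_mix={"rl": 1.0},
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_trial_log(rng, n_trials=40, p_rating=0.4, both_arms=False,
                     subject="s1", block=1):
    """A structurally valid random trial log for preprocessing tests."""
    import pandas as pd

    rows = []
    for t in range(1, n_trials + 1):
        is_rating = rng.random() < p_rating
        arm = int(rng.integers(0, 2))
        row = dict(subject=subject, block=block, trial=t,
                   trial_type="rating" if is_rating else "choice", arm=arm,
                   outcome=np.nan, value_rating=np.nan, belief_conf=np.nan,
                   value_rating_other=np.nan, belief_conf_other=np.nan,
                   decision_conf=np.nan, rt_ms=np.nan)
        if is_rating:
            row["value_rating"] = float(rng.uniform(0, 100))
            row["belief_conf"] = float(rng.uniform(0, 1))
            if rng.random() < 0.5:
                row["outcome"] = float(rng.uniform(0, 100))
            if both_arms:
                row["value_rating_other"] = float(rng.uniform(0, 100))
                row["belief_conf_other"] = float(rng.uniform(0, 1))
        else:
            row["decision_conf"] = float(rng.uniform(0, 1))
            row["rt_ms"] = float(rng.uniform(300, 2000))
            row["outcome"] = float(rng.uniform(0, 100))
        rows.append(row)
    return pd.DataFrame(rows)
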