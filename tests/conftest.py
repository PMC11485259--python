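import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=50)
settings.load_profile("suite")

from lipidscore import (ScoreDefinition, generate_ground_truth, simulate_cohort,
                        simulate_trial)
from lipidscore.lipids import LipidMatrix


@pytest.fixture(scope="session")
def small_gt():
    return generate_ground_truth(p=10, n_affected=4, graph_density=0.15,
                                 effect_scale=0.6, seed=101,
                                 hazard_coef=np.log(0.68), baseline_hazard=0.01)


@pytest.fixture(scope="session")
def small_trial(small_gt):
    return simulate_trial(small_gt, (80, 160), seed=202)


@pytest.fixture(scope="session")
def small_score(small_gt):
    names = tuple(small_gt.variables[i] for i in small_gt.affected)
    weights = tuple(float(small_gt.delta[i]) for i in small_gt.affected)
    return ScoreDefinition(variables=names, weights=weights, scale=1.0)


@pytest.fixture(scope="session")
def small_cohort(small_gt, small_score):
    return simulate_cohort(small_gt, 2000, 10.0, small_score, seed=303)


@pytest.fixture()
def raw_matrix():
    rng = np.random.default_rng(7)
    cols = ["CE(16:0)", "CE(18:1)", "DAG(16:0/18:1)", "DAG(16:1/18:0)", "DAG(16:0/16:0)"]
    vals = np.exp(rng.standard_normal((30, len(cols))))
    return LipidMatrix(pd.DataFrame(vals, columns=cols,
                                    index=pd.Index([f"s{i}" for i in range(30)], name="sample_id")))
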