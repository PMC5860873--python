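import numpy as np
import pytest
from hypothesis import settings

import placebayes as pb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject cohort, all generated under the Bayesian model."""
    cfg = pb.CohortConfig(seed=11, n_htp=6, n_ltp=6)
    trials, truth = pb.simulate_cohort(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def small_chain(small_cohort):
    """Full fit -> integrate -> evidence chain on the small cohort."""
    _, trials, truth = small_cohort
    fits = pb.fit_all_subjects(trials)
    models = pb.compute_models(fits)
    evidence = pb.compute_evidence(trials, models)
    return trials, truth, fits, models, evidence


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
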