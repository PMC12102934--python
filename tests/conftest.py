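import numpy as np
import pytest
from hypothesis import settings

import actipheno as ap
from actipheno.cffs import CffsParams
from actipheno.synth import identity_effect, psf_like

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

RECOVERY_SEEDS = tuple(range(11, 21))
NULL_SEEDS = tuple(range(21, 31))

# the recovery protocol: logistic-regression clique ensemble (fast,
# deterministic); the scaled greedy ensemble is defined in the tests
RECOVERY_CFFS = dict(algorithms=("LR",))


def make_table(effect, seed):
    subjects, labels = ap.generate_cohort(25, 22, effect=effect, seed=seed)
    return ap.build_feature_table(subjects, labels)


@pytest.fixture(scope="session")
def psf_tables():
    """Feature tables for ten case/control cohorts carrying the
    positive-schizotypy-like effect (longer small peaks, sparser large
    ones), one per seed."""
    return {seed: make_table(psf_like(), seed) for seed in RECOVERY_SEEDS}


@pytest.fixture(scope="session")
def null_tables():
    """Feature tables for ten effect-free cohorts."""
    return {seed: make_table(identity_effect(), seed) for seed in NULL_SEEDS}


@pytest.fixture(scope="session")
def psf_table(psf_tables):
    """One representative planted-effect cohort."""
    return psf_tables[RECOVERY_SEEDS[0]]


@pytest.fixture(scope="session")
def cffs_model_batch(psf_table):
    """A moderate batch of trained clique models on the representative
    cohort, shared by the accuracy-gate and Shapley-axiom tests."""
    from actipheno.cffs import run_cffs

    params = CffsParams(algorithms=("LR", "ANN"), max_cliques=40, seed=5)
    return run_cffs(psf_table, params)
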