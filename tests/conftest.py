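"""Shared fixtures: small seeded synthetic cohorts and fitted components.

Everything is generated programmatically; the session-scoped fixtures cache
the expensive fits (transition classifiers) so the suite stays fast.
"""

import numpy as np
import pytest

import oncotwin as ot


@pytest.fixture(scope="session")
def compact_cohort():
    """Compact-schema stochastic cohort, n=240, fixed seed."""
    cfg = ot.GeneratorConfig(n=240, seed=101, schema="compact")
    return ot.generate_cohort(cfg)


@pytest.fixture(scope="session")
def split_preprocessed(compact_cohort):
    train, test = ot.split_cohort(compact_cohort, 0.75, seed=7)
    pre = ot.Preprocessor(compact_cohort.schema).fit(train)
    return pre.transform(train), pre.transform(test), pre


@pytest.fixture(scope="session")
def noiseless_setup():
    """Deterministic-transition cohort with a fitted simulator."""
    cfg = ot.GeneratorConfig.noiseless(n=600, seed=11)
    table = ot.generate_cohort(cfg)
    train, test = ot.split_cohort(table, 0.75, seed=2)
    pre = ot.Preprocessor(table.schema).fit(train)
    tr, te = pre.transform(train), pre.transform(test)
    twin = ot.TreatmentSimulator(tr, pre).fit(seed=0)
    gen = ot.CohortGenerator(cfg)
    gen.generate()
    return {"train": tr, "test": te, "pre": pre, "twin": twin, "generator": gen}


@pytest.fixture(scope="session")
def fitted_twin_stochastic(split_preprocessed):
    train, test, pre = split_preprocessed
    twin = ot.TreatmentSimulator(train, pre).fit(seed=0)
    return twin


@pytest.fixture
def rng():
    return np.random.default_rng(0)
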