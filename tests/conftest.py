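"""Shared fixtures: simulated cohorts and trained maps (session-scoped).

The heavyweight objects (default fixture cohorts and their 40x40 maps) are
trained once per session and shared between unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from agesom import (
    SOMPortrayal,
    expression_fixture_spec,
    generate_cohort,
    group_mean_portraits,
    methylation_fixture_spec,
)
from agesom.preprocess import (
    MethylationInput,
    aggregate_promoter,
    beta_to_mratio,
    centralize,
)


def methylation_matrix(cohort):
    """Promoter aggregation -> logit transform -> centralization."""
    agg, _ = aggregate_promoter(MethylationInput(cohort.beta, cohort.cpg_annotation))
    return centralize(beta_to_mratio(agg), layer="methylation_log_ratio")


@pytest.fixture(scope="session")
def exp_cohort():
    return generate_cohort(expression_fixture_spec(seed=1))


@pytest.fixture(scope="session")
def exp_matrix(exp_cohort):
    return centralize(exp_cohort.expression)


@pytest.fixture(scope="session")
def exp_model(exp_matrix):
    return SOMPortrayal(seed=1).fit(exp_matrix)


@pytest.fixture(scope="session")
def exp_groups(exp_cohort):
    return exp_cohort.metadata["group"].to_dict()


@pytest.fixture(scope="session")
def exp_group_portraits(exp_model, exp_groups, exp_cohort):
    return group_mean_portraits(exp_model.portraits(), exp_groups, exp_cohort.scheme)


@pytest.fixture(scope="session")
def meth_cohort():
    return generate_cohort(methylation_fixture_spec(seed=1))


@pytest.fixture(scope="session")
def meth_matrix(meth_cohort):
    return methylation_matrix(meth_cohort)


@pytest.fixture(scope="session")
def meth_model(meth_matrix):
    return SOMPortrayal(seed=1).fit(meth_matrix)


@pytest.fixture(scope="session")
def meth_group_portraits(meth_model, meth_cohort):
    groups = meth_cohort.metadata["group"].to_dict()
    return group_mean_portraits(meth_model.portraits(), groups, meth_cohort.scheme)


@pytest.fixture(scope="session")
def meth_model_on_exp_cohort(exp_cohort):
    """M-layer map of the expression cohort (for cross-map melting)."""
    return SOMPortrayal(seed=1).fit(methylation_matrix(exp_cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_matrix(rng):
    """Small random centralized matrix for oracle-equivalence checks."""
    vals = rng.normal(size=(50, 10))
    df = pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(50)],
        columns=[f"s{j}" for j in range(10)],
    )
    return centralize(df)
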