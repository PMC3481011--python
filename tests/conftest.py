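import numpy as np
import pandas as pd
import pytest

from implinet.model import DifferentialCoexpressionModel
from implinet.synthetic import CohortConfig, generate_expression_cohort


def make_cohort_pair(seed: int, **overrides):
    """Training + independent test cohort sharing the same planted truth."""
    train = CohortConfig(seed=seed, **overrides)
    test = CohortConfig(seed=seed + 10_000, **overrides)
    expr, clin, truth = generate_expression_cohort(train)
    expr_t, clin_t, _ = generate_expression_cohort(test)
    expr_t.columns = [f"T{c}" for c in expr_t.columns]
    clin_t = clin_t.copy()
    clin_t.index = expr_t.columns
    clin_t["sample_id"] = clin_t.index
    return expr, clin, expr_t, clin_t, truth


@pytest.fixture(scope="session")
def default_cohort_pair():
    return make_cohort_pair(7)


@pytest.fixture(scope="session")
def fitted_results(default_cohort_pair):
    expr, clin, expr_t, clin_t, truth = default_cohort_pair
    model = DifferentialCoexpressionModel(
        expr, clin, truth.hub_genes, expr_t, clin_t
    )
    return model.fit(), truth


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for I/O and plumbing tests."""
    cfg = CohortConfig(
        n_smokers=40, n_nonsmokers=40, n_background_genes=20, seed=42
    )
    return generate_expression_cohort(cfg)
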