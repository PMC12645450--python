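import numpy as np
import pandas as pd
import pytest

import perturbnet as pn

# a small cohort for fast tests: same structure as the default study
# conditions, scaled down
SMALL = dict(
    n_genes=300,
    n_reference=10,
    samples_per_subtype=(12, 12, 12),
    n_nodes=60,
    n_attach=8,
    n_perturbed_edges_per_subtype=15,
    seed=7,
)


def make_expression(values, genes=None, samples=None, condition=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    cond = None
    if condition is not None:
        cond = pd.Series(list(condition), index=samples, name="condition")
    return pn.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), condition=cond
    )


@pytest.fixture(scope="session")
def small_cohort():
    return pn.generate_cohort(pn.SyntheticCohortConfig(**SMALL))


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default study conditions (2,000 genes, 20 ref, 3x40)."""
    return pn.generate_cohort(pn.SyntheticCohortConfig(seed=1))


def perturbation_pipeline(cohort):
    ranks = pn.rank_transform(cohort.expression)
    delta = pn.delta_rank(ranks, cohort.network)
    pert = pn.perturbation_matrix(
        delta, cohort.expression.samples_with("reference")
    )
    return ranks, delta, pert


@pytest.fixture(scope="session")
def default_perturbation(default_cohort):
    return perturbation_pipeline(default_cohort)


@pytest.fixture(scope="session")
def default_filtered(default_cohort, default_perturbation):
    _, _, pert = default_perturbation
    return pn.select_perturbed_edges(pert, default_cohort.expression.condition)


@pytest.fixture(scope="session")
def small_perturbation(small_cohort):
    return perturbation_pipeline(small_cohort)
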