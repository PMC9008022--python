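import numpy as np
import pandas as pd
import pytest

from ccimap.io_qc import ExpressionMatrix, lognormalize, qc_filter
from ccimap.simulate import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_counts(rng):
    """Random 50x20 count matrix, raw_counts layer."""
    values = rng.poisson(2.0, size=(50, 20)).astype(float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(50)],
        [f"c{j}" for j in range(20)],
        layer="raw_counts",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The reference synthetic cohort (defaults, seed 1), generated once."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    """(cohort, post-QC lognorm matrix) pair shared across tests."""
    filtered = qc_filter(default_cohort.matrix)
    return default_cohort, lognormalize(filtered)


def make_labeled_matrix(rng, n_genes=30, groups=(("A", 10), ("B", 10), ("C", 10)), shift_genes=None):
    """Lognorm matrix with optional per-group mean shifts on chosen genes.

    shift_genes: dict group -> (gene indices, added lognorm value).
    Returns (ExpressionMatrix, labels Series).
    """
    n_obs = sum(n for _, n in groups)
    values = rng.gamma(2.0, 0.5, size=(n_genes, n_obs))
    labels = []
    col = 0
    for name, n in groups:
        if shift_genes and name in shift_genes:
            idx, amount = shift_genes[name]
            values[np.ix_(np.asarray(idx), np.arange(col, col + n))] += amount
        labels += [name] * n
        col += n
    m = ExpressionMatrix(
        values,
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_obs)],
        layer="lognorm",
    )
    return m, pd.Series(labels, index=m.obs_ids)
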