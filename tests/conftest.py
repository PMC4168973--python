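import numpy as np
import pandas as pd
import pytest

from pathsurv.io import ExpressionMatrix, SurvivalOutcome
from pathsurv.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small pathway-structured cohort with two causal pathways."""
    cfg = SimulationConfig(
        n_samples=80, n_pathways=12, genes_per_pathway=8, n_causal_pathways=2, seed=42
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_pds(small_cohort):
    from pathsurv.pds import compute_pds_matrix

    expr, sets, _, _, _ = small_cohort
    return compute_pds_matrix(expr, sets)


@pytest.fixture
def tiny_expression():
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0], [3.5, 4.25], [5.0, 6.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2"],
        )
    )


def make_survival(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalOutcome(pd.DataFrame({"time": times, "event": events}, index=ids))


@pytest.fixture
def ph_data():
    """Simulated proportional-hazards data with a known 3-feature effect."""
    rng = np.random.default_rng(11)
    n = 50
    X = rng.standard_normal((n, 3))
    beta = np.array([0.8, -0.5, 0.0])
    t = -np.log(rng.random(n)) / (0.3 * np.exp(X @ beta))
    c = rng.uniform(0, 8, n)
    return X, np.minimum(t, c), (t <= c).astype(int)
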