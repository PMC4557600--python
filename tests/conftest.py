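import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mirlink as ml

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic experiment (two cultures, 20 planted edges)."""
    cfg = ml.SimConfig()
    mi, mr, design, truth = ml.simulate_experiment(cfg, seed=11)
    return cfg, mi, mr, design, truth


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale experiment for fast unit tests."""
    cfg = ml.SimConfig(n_mirna=12, n_mrna=60, n_edges=5, n_de_mirna=3,
                       n_de_mrna=10, cell_lines=("HN1957",))
    mi, mr, design, truth = ml.simulate_experiment(cfg, seed=5)
    return cfg, mi, mr, design, truth


@pytest.fixture()
def tiny_matrix():
    """Hand-sized matrix with one cell line, 2 conditions x 2 bio x 2 tech."""
    design = ml.SampleDesign.default_layout(("CL",), n_bio=2, n_tech=2)
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8, 1, size=(6, 8)),
        index=[f"f{i}" for i in range(6)],
        columns=design.sample_ids,
    )
    return ml.ExpressionMatrix(values, "mRNA"), design
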