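import numpy as np
import pandas as pd
import pytest

from coexmerge.preprocess import CASE, CONTROL, ExpressionStudy, zscore_merge
from coexmerge.synthetic_data import SimulationConfig, simulate_studies


@pytest.fixture(scope="session")
def planted_sim():
    """Standard planted scenario: 2 studies, 40 DE genes, 10 DC pairs."""
    cfg = SimulationConfig(seed=11)
    studies, truth = simulate_studies(cfg)
    return cfg, studies, truth


@pytest.fixture(scope="session")
def merged_planted(planted_sim):
    _, studies, _ = planted_sim
    return zscore_merge(studies)


@pytest.fixture(scope="session")
def null_sim():
    """No planted structure at all."""
    cfg = SimulationConfig(n_de_genes=0, n_dc_pairs=0, seed=17)
    studies, truth = simulate_studies(cfg)
    return cfg, studies, truth


def make_study(values, n_case, n_ctrl, study_id="s1", genes=None):
    """Small hand-built study: values is genes x samples, cases first."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_ctrl)]
    expr = pd.DataFrame(values, index=genes, columns=cols)
    condition = pd.Series([CASE] * n_case + [CONTROL] * n_ctrl, index=cols)
    return ExpressionStudy(study_id=study_id, expr=expr, condition=condition)
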