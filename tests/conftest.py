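import numpy as np
import pandas as pd
import pytest

from asra.data_model import ExpressionMatrix
from asra.synthetic import PlantConfig, generate_training


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down planted design used by fast recovery tests."""
    return PlantConfig(
        n_genes=400,
        n_asra_up=10,
        n_asra_down=2,
        n_exclusive=2,
        n_absent_any=4,
        n_a_up=20,
        n_a_down=15,
        n_b_up=10,
        n_b_down=5,
        n_a_up_b_down=2,
        n_a_down_b_up=2,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return generate_training(small_cfg)


@pytest.fixture(scope="session")
def default_discovery():
    """Full-scale discovery run on the default planted design (shared)."""
    from asra.pipeline import PipelineConfig, run_discovery

    cfg = PlantConfig()  # seed 0
    x, truth = generate_training(cfg)
    table, summary, diffs = run_discovery(x, PipelineConfig(seed=cfg.seed))
    return x, truth, table, summary, diffs


def make_matrix(values, genes=None, samples=None, conditions=None, calls=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    calls_df = None
    if calls is not None:
        calls_df = pd.DataFrame(np.asarray(calls, dtype=object), index=genes, columns=samples)
    cond = pd.Series(conditions, index=samples) if conditions is not None else None
    return ExpressionMatrix(values=df, calls=calls_df, conditions=cond)


@pytest.fixture
def toy_two_group():
    """6 genes x 5 samples (3 'A' vs 2 'B') with a clear group difference."""
    rng = np.random.default_rng(7)
    base = rng.normal(8, 1, size=(6, 5))
    base[:3, :3] += 2.0  # first 3 genes up in group A
    return make_matrix(base, conditions=["A", "A", "A", "B", "B"])
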