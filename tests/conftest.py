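import numpy as np
import pandas as pd
import pytest

from dosetx import preprocess, simulate
from dosetx.datamodel import ExpressionMatrix, make_design


@pytest.fixture(scope="session")
def small_planted():
    """A small planted experiment shared by read-only tests (seeded)."""
    cfg = simulate.GeneratorConfig(n_genes=2000, seed=11)
    probe, design, truth = simulate.generate_probe_data(cfg)
    expr = preprocess.preprocess_probe_data(probe)
    return probe, design, truth, expr


@pytest.fixture()
def zero_noise_config():
    return simulate.GeneratorConfig(
        n_genes=100,
        baseline_sd_between_genes=0.0,
        replicate_sd=0.0,
        probe_sd=0.0,
        probe_offset_sd=0.3,
        seed=3,
    )


@pytest.fixture()
def tiny_expr():
    """3 genes x (2 potencies x 2 agents x 2 replicates) with hand-set values."""
    design = make_design((2, 3), replicates=2)
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        rng.normal(8, 1, (3, len(design))),
        index=["gA", "gB", "gC"],
        columns=[s.sample_id for s in design],
    )
    return ExpressionMatrix(data, tuple(design))
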