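import numpy as np
import pandas as pd
import pytest

from aegmap.synthetic import CnvBlock, SimConfig, generate_scrna


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced study configuration for fast unit tests.

    Same structure as the default conditions (20% of genes in CNV blocks
    at |log2| >= 0.6, disjoint programs, mito panel) at ~1/4 scale.
    """
    params = dict(
        n_cells=600,
        n_genes=1000,
        frac_malignant=0.2,
        cnv_blocks=[
            CnvBlock("chr2", 10, 60, 1.0),
            CnvBlock("chr5", 0, 50, -1.0),
            CnvBlock("chr8", 20, 50, 0.8),
            CnvBlock("chr10", 0, 40, -0.7),
        ],
        program_size=80,
        malignancy_program_size=100,
        normal_program_size=180,
        n_planted_de=180,
        markers_per_type=50,
        n_ref_cells=150,
        cohort_size=120,
        n_spots=100,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config(seed=0)


@pytest.fixture(scope="session")
def small_scrna(small_cfg):
    return generate_scrna(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_expr() -> pd.DataFrame:
    """3 cells x 4 genes with known rank structure."""
    return pd.DataFrame(
        [[5.0, 3.0, 1.0, 0.0], [2.0, 2.0, 1.0, 0.0], [0.0, 1.0, 2.0, 3.0]],
        index=["c1", "c2", "c3"],
        columns=["g1", "g2", "g3", "g4"],
    )
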