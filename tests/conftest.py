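import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from multicia.blocks import OmicsBlock
from multicia.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 7)."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for cheap end-to-end checks."""
    cfg = SyntheticConfig(
        n_per_group={"positive": 10, "control": 10, "progressive": 4},
        features_per_block={
            "pbmc_smallseq": 120,
            "csf_cells_methylome": 150,
            "plasma_smallseq": 80,
            "csf_cells_smallseq": 60,
            "csf_free_mintmap": 50,
        },
        seed=11,
    )
    return cfg, generate_cohort(cfg)


def make_count_block(counts, assay="smallseq", source="plasma", samples=None):
    counts = np.asarray(counts, dtype=float)
    n, p = counts.shape
    samples = samples or [f"s{i}" for i in range(n)]
    df = pd.DataFrame(counts, index=samples, columns=[f"g{j}" for j in range(p)])
    return OmicsBlock(df, assay=assay, source=source)


def make_methyl_block(values, source="csf_cells", samples=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    df = pd.DataFrame(values, index=samples, columns=[f"cpg{j}" for j in range(p)])
    return OmicsBlock(df, assay="methylome", source=source)
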