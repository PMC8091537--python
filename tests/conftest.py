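import numpy as np
import pandas as pd
import pytest

from tlv import SyntheticConfig, generate, mva_scale, stats_table
from tlv.matrix_io import filter_low_counts
from tlv.scaling import median_of_ratios_size_factors


@pytest.fixture
def toy_matrix() -> pd.DataFrame:
    """3 genes x 4 samples with simple hand-checkable values."""
    return pd.DataFrame(
        [[2.0, 4.0, 6.0, 8.0],
         [5.0, 5.0, 5.0, 5.0],
         [1.0, 10.0, 3.0, 7.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (800 genes, 35 samples) plus ground truth.

    Session-scoped: generation and the stats table are reused across test
    modules; tests must not mutate it.
    """
    cfg = SyntheticConfig(n_genes=800, seed=20240601)
    matrix, truth = generate(cfg)
    kept = filter_low_counts(matrix).matrix
    scaled = mva_scale(kept, size_factors=median_of_ratios_size_factors(kept))
    stats = stats_table(scaled, raw=kept)
    return {"config": cfg, "matrix": matrix, "kept": kept,
            "scaled": scaled, "stats": stats, "truth": truth}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
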