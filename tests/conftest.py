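import numpy as np
import pandas as pd
import pytest

from mrlink.instruments import HarmonizedSet
from mrlink.summary_io import SummaryStatsTable


def make_table(rows, trait_id="t", trait_type="continuous"):
    """Build a SummaryStatsTable from dict rows with canonical keys."""
    return SummaryStatsTable(trait_id, trait_type, pd.DataFrame(rows))


@pytest.fixture
def three_ratio_hset():
    """Wald ratios/SEs exactly {(2.0, 0.5), (1.0, 1.0), (3.0, 0.25)}.

    beta_exp = 1 everywhere so beta_out is the ratio and se_out its SE.
    """
    return HarmonizedSet(
        ["rs1", "rs2", "rs3"],
        [1.0, 1.0, 1.0], [0.1, 0.1, 0.1],
        [2.0, 1.0, 3.0], [0.5, 1.0, 0.25],
    )


@pytest.fixture
def five_snp_hset():
    """Five instruments with unequal weights for median/mode fixtures."""
    return HarmonizedSet(
        [f"rs{i}" for i in range(5)],
        [0.9, 1.1, 1.0, 0.8, 1.2], [0.05] * 5,
        [0.8, 1.0, 1.2, 1.5, 3.0],
        [0.4, 0.2, 0.1, 0.5, 1.0],
    )


@pytest.fixture
def random_hset():
    rng = np.random.default_rng(7)
    j = 12
    be = rng.normal(0.1, 0.03, j)
    be[np.abs(be) < 0.02] = 0.05
    return HarmonizedSet(
        [f"rs{i}" for i in range(j)],
        be, np.abs(rng.normal(0.01, 0.002, j)) + 1e-3,
        rng.normal(0.05, 0.05, j), np.abs(rng.normal(0.05, 0.01, j)) + 1e-3,
    )
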