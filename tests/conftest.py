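import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from snpenrich.gwas import SnpPanel
from snpenrich.synthetic import SimConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale study: 2 x 2 Mb, 3000 SNPs, 8 true + 8 decoy clusters."""
    return SimConfig(
        seed=11,
        n_chrom=2,
        chrom_length=2_000_000,
        n_snps=3000,
        n_samples=200,
        n_true_clusters=8,
        n_decoy_clusters=8,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


def make_panel(positions, chrom="chr1", pvalues=None, maf=None, ids=None):
    n = len(positions)
    df = pd.DataFrame(
        {
            "snp_id": ids if ids is not None else [f"rs{i}" for i in range(n)],
            "chrom": chrom if isinstance(chrom, str) else chrom,
            "pos": positions,
            "pvalue": pvalues if pvalues is not None else np.full(n, 0.5),
            "maf": maf if maf is not None else np.full(n, 0.25),
        }
    )
    return SnpPanel(df)
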