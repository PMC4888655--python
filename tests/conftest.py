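import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hmcscan as h

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle_small():
    """Small full dataset: 150 genes, 1 chromosome, 60 enhancers."""
    cfg = h.SyntheticConfig(n_chroms=1, chrom_length=4_000_000, n_genes=150,
                            n_enhancers=60, seed=11)
    return h.simulate(cfg)


@pytest.fixture(scope="session")
def bundle_mid():
    """Mid-size dataset for correlation/tertile checks: 2000 genes."""
    cfg = h.SyntheticConfig(n_chroms=2, chrom_length=12_000_000, n_genes=2000,
                            n_enhancers=100, seed=7)
    return h.simulate(cfg)


@pytest.fixture(scope="session")
def bundle_tf():
    """Enhancer-heavy dataset: 1000 enhancers (500 per 5hmC group)."""
    cfg = h.SyntheticConfig(n_chroms=2, chrom_length=10_000_000, n_genes=100,
                            n_enhancers=1000, frac_positive_enhancers=0.5,
                            tf_effect=3.0, seed=23)
    return h.simulate(cfg)


@pytest.fixture
def toy_table():
    """Hand-built site table on one chromosome."""
    df = pd.DataFrame({
        "chrom": "chr1",
        "pos": [100, 200, 300, 400, 500, 600],
        "strand": "+",
        "count": [10, 0, 30, 0, 150, 101],
    })
    return h.SiteTable(df, library_id="toy", cell_type="toy")


def make_gene(gene_id="g0", chrom="chr1", strand="+", start=1000, end=9000, exons=None):
    exons = exons or [(start, start + 2000), (end - 2000, end)]
    return h.GeneModel(gene_id, chrom, strand, start, end, exons)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
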