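import numpy as np
import pandas as pd
import pytest

from pleiocov import GenotypePanel, MISSING


def make_panel(dosages, chrom=None, start_pos=1000, spacing=500):
    """Small GenotypePanel straight from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    p = dosages.shape[1]
    chrom = np.full(p, 1) if chrom is None else np.asarray(chrom)
    pos = np.empty(p, dtype=int)
    for c in np.unique(chrom):
        k = (chrom == c).sum()
        pos[chrom == c] = start_pos + spacing * np.arange(k)
    snp_map = pd.DataFrame(
        {"snp": [f"rs{j}" for j in range(p)], "chrom": chrom, "pos": pos,
         "a1": "A", "a2": "G"}
    )
    return GenotypePanel(dosages=dosages, snp_map=snp_map)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_panel():
    """3 individuals x 2 SNPs, one missing call."""
    return make_panel([[0, 2], [1, MISSING], [2, 1]])


def random_panel(rng, n=30, p=20, missing_frac=0.0):
    dos = rng.integers(0, 3, size=(n, p)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random((n, p)) < missing_frac
        # keep at least one observed call per SNP
        mask[0, :] = False
        dos[mask] = MISSING
    return make_panel(dos)
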