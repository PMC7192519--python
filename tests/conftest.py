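import numpy as np
import pytest

from coloctools import simulate as sim


@pytest.fixture(scope="session")
def panel():
    """Shared synthetic reference panel (10 LD blocks of 20 SNPs)."""
    return sim.synth_haplotype_panel(M=200, block_size=20, seed=1)


@pytest.fixture(scope="session")
def panel_ld(panel):
    """Panel-level signed LD (from the haplotypes themselves)."""
    return sim.genotype_ld(panel.haplotypes.astype(float), panel.snp_ids)


def pick_independent_pair(panel, rng, r2max=0.01):
    """Two common SNPs with panel r2 below ``r2max`` (distinct LD blocks)."""
    ld = np.corrcoef(panel.haplotypes.T.astype(float))
    idx = {s: i for i, s in enumerate(panel.snp_ids)}
    common = panel.common_snps()
    while True:
        a, b = rng.choice(common, 2, replace=False)
        if ld[idx[a], idx[b]] ** 2 < r2max:
            return str(a), str(b)
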