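import numpy as np
import pandas as pd
import pytest

from crisprqtl.simulate import LdBlockSpec, simulate_genotypes


def make_gwas_frame(n=10, seed=0, chrom="3", start=45_000_000, step=1000):
    """A small valid GWAS summary-statistic table."""
    rng = np.random.default_rng(seed)
    alleles = [("A", "G"), ("C", "T")] * ((n + 1) // 2)
    return pd.DataFrame({
        "chrom": chrom,
        "pos": start + step * np.arange(n),
        "ref": [a[0] for a in alleles[:n]],
        "alt": [a[1] for a in alleles[:n]],
        "beta": rng.normal(size=n),
        "se": rng.uniform(0.05, 0.2, size=n),
        "pvalue": rng.uniform(1e-8, 1.0, size=n),
    })


@pytest.fixture(scope="session")
def small_block():
    """A reusable small LD block (500 individuals x 50 variants)."""
    return simulate_genotypes(LdBlockSpec(n_individuals=500, n_variants=50, seed=11))


@pytest.fixture
def gwas_frame():
    return make_gwas_frame()
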