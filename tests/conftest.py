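import numpy as np
import pandas as pd
import pytest

from homeoscan import simdata


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset shared by read-only tests."""
    cfg = simdata.SimConfig(n_genes=60, seed=42)
    return simdata.simulate_dataset(cfg)


def make_variant_table(genotypes, sexes, qual=40.0, depth=30, transcript="t1", length=1000):
    """VariantTable from a genotype matrix (sites x individuals) with exact depths."""
    from homeoscan.genotypes import GT_HET, GT_HOM_ALT, VariantTable

    gt = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = gt.shape
    ref = np.full(gt.shape, depth)
    alt = np.zeros(gt.shape, dtype=int)
    alt[gt == GT_HET] = depth // 2
    ref[gt == GT_HET] = depth - depth // 2
    alt[gt == GT_HOM_ALT] = depth
    ref[gt == GT_HOM_ALT] = 0
    sites = pd.DataFrame(
        {
            "transcript": [transcript] * n_sites,
            "pos": np.arange(1, n_sites + 1),
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
            "qual": [qual] * n_sites,
        }
    )
    return VariantTable(
        samples=[f"s{i}" for i in range(n_ind)],
        sex=list(sexes),
        sites=sites,
        ref_depth=ref,
        alt_depth=alt,
        genotypes=gt,
        assayable={transcript: length},
    )
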