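import numpy as np
import pandas as pd
import pytest

from xtrait import simulate


@pytest.fixture(scope="session")
def small_panel():
    """10 blocks x 50 SNPs, AR(1) decay gradient."""
    return simulate.make_panel(n_blocks=10, block_size=50, seed=11)


@pytest.fixture(scope="session")
def nold_panel():
    """LD-free panel (identity correlation everywhere)."""
    return simulate.make_panel(n_blocks=10, block_size=50, ar1_rho=0.0, seed=12)


@pytest.fixture(scope="session")
def acc_panel():
    """The 100x200 (M=20,000) panel used by the recovery experiments."""
    return simulate.make_panel(n_blocks=100, block_size=200, seed=1)


def canonical_frame(n=5, chrom=1, seed=0, **overrides):
    """A small valid canonical sumstats DataFrame."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    eaf = rng.uniform(0.1, 0.9, n)
    nn = np.full(n, 10_000.0)
    se = 1.0 / np.sqrt(2 * eaf * (1 - eaf) * (nn + z ** 2))
    from scipy import stats
    df = pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": chrom,
        "pos": np.arange(1, n + 1) * 1000,
        "a1": "A", "a2": "G",
        "eaf": eaf, "beta": z * se, "se": se, "z": z,
        "p": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
        "n": nn,
    })
    for k, v in overrides.items():
        df[k] = v
    return df


@pytest.fixture
def trait_pair():
    from xtrait.sumstats import from_frame
    g1 = from_frame("t1", canonical_frame(20, seed=1))
    g2 = from_frame("t2", canonical_frame(20, seed=2))
    return g1, g2
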