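import numpy as np
import pandas as pd
import pytest

from tumordiv import copy_number as cn
from tumordiv import synthetic


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = synthetic.SimCNConfig(
        n_participants=3, noise_sd=0.0, purity_range=(0.4, 0.8), seed=11
    )
    profiles, truth = synthetic.simulate_cn_cohort(cfg)
    return cfg, profiles, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    cfg = synthetic.SimCNConfig(n_participants=3, noise_sd=0.1, seed=17)
    profiles, truth = synthetic.simulate_cn_cohort(cfg)
    return cfg, profiles, truth


def make_profile(log2, chrom=None, sample_id="S"):
    """Tiny BinProfile on a single chromosome unless chrom given."""
    log2 = np.asarray(log2, dtype=float)
    n = len(log2)
    if chrom is None:
        chrom = np.array(["chr1"] * n, dtype=object)
    else:
        chrom = np.asarray(chrom, dtype=object)
    start = np.zeros(n, dtype=int)
    for c in pd.unique(chrom):
        m = chrom == c
        start[m] = np.arange(m.sum()) * 500_000 + 1
    return cn.BinProfile(
        sample_id=sample_id, chrom=chrom, start=start, end=start + 499_999, log2=log2
    )


@pytest.fixture
def step_profile():
    """40-bin noise-free profile with one step of height 1.0 at bin 20."""
    return make_profile(np.r_[np.zeros(20), np.ones(20)])
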