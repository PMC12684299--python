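import numpy as np
import pandas as pd
import pytest

from islepop.containers import GenotypeMatrix
from islepop.simdata import SimConfig


def make_gm(gt, dp=None, minor_ad=None, chrom=None, pos=None, ref=None, alt=None):
    """Small GenotypeMatrix from arrays, filling in boilerplate site info."""
    gt = np.asarray(gt, dtype=np.int8)
    n_samples, n_sites = gt.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * n_sites,
            "pos": pos if pos is not None else np.arange(1, n_sites + 1) * 1000,
            "ref": ref if ref is not None else ["A"] * n_sites,
            "alt": alt if alt is not None else ["G"] * n_sites,
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        sites=sites,
        gt=gt,
        dp=None if dp is None else np.asarray(dp),
        minor_ad=None if minor_ad is None else np.asarray(minor_ad),
    )


@pytest.fixture
def toy_gm():
    """4 samples x 6 sites with depth fields, mean depth 30 per sample."""
    gt = np.array(
        [
            [0, 1, 2, 1, 0, 1],
            [1, 1, 0, 0, 2, 0],
            [2, 0, 1, 1, 1, 2],
            [0, 0, 0, 2, 1, 1],
        ],
        dtype=np.int8,
    )
    dp = np.full(gt.shape, 30, dtype=np.int32)
    minor = np.where(gt == 1, 15, 0).astype(np.int32)
    return make_gm(gt, dp=dp, minor_ad=minor)


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Fast two-population scenario for integration tests (seconds, not minutes)."""
    return SimConfig(
        n_mainland=60,
        n_island=10,
        split_generation=50,
        total_generations=60,
        chrom_length_bp=1_000_000,
        n_chromosomes=2,
        mu=1e-7,
        n_sample_mainland=4,
        n_sample_island=4,
        seed=0,
    )
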