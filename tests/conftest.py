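import numpy as np
import pandas as pd
import pytest

from poolmeth import CpGCountTable, ReferenceMethylome


def make_table(rows, chrom="chr1"):
    """rows: iterable of (pos, c, t)."""
    df = pd.DataFrame(rows, columns=["pos", "c", "t"])
    df.insert(0, "chrom", chrom)
    return CpGCountTable(df)


def make_reference(values, chrom="chr1", start=100, step=50):
    pos = start + step * np.arange(len(values))
    return ReferenceMethylome(
        pd.DataFrame({"chrom": chrom, "pos": pos, "m": values}))


def random_table(rng, n_sites=50, max_cov=30, chrom="chr1"):
    pos = np.sort(rng.choice(np.arange(100, 100_000), n_sites, replace=False))
    n = rng.integers(0, max_cov + 1, n_sites)
    t = rng.binomial(n, rng.uniform(0, 0.3))
    return CpGCountTable(pd.DataFrame(
        {"chrom": chrom, "pos": pos, "c": n - t, "t": t}))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
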