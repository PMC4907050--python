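import numpy as np
import pytest

from croaker_gs.genotype_data import (
    GenotypeMatrix,
    allele_frequencies,
    compute_marker_stats,
    standardize,
)
import pandas as pd


def make_matrix(codes, missing=None, chrom=None, pos=None):
    """GenotypeMatrix from a plain array, generating ids."""
    codes = np.asarray(codes, dtype=float)
    n, p = codes.shape
    markers = pd.DataFrame({
        "marker_id": [f"m{j}" for j in range(p)],
        "chrom": chrom if chrom is not None else ["1"] * p,
        "pos": pos if pos is not None else np.arange(1, p + 1),
    })
    if missing is None:
        missing = np.zeros((n, p), dtype=bool)
    return GenotypeMatrix([f"s{i}" for i in range(n)], markers, codes, missing)


def random_training_fixture(rng, n, p, h2=0.5):
    """Random polymorphic dosage data + phenotype with sex, for solver tests."""
    f = rng.uniform(0.1, 0.5, size=p)
    codes = rng.binomial(2, f, size=(n, p)).astype(float)
    freqs = allele_frequencies(codes)
    keep = (freqs > 0) & (freqs < 1)
    codes, freqs = codes[:, keep], freqs[keep]
    xs = standardize(codes, freqs=freqs)
    sex = np.tile([1, 2], (n + 1) // 2)[:n]
    y = rng.normal(size=n) + 0.3 * (sex == 2)
    return codes, freqs, xs, sex, y


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
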