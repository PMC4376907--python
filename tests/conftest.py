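import numpy as np
import pytest

from gbskit.snpmatrix import MISSING, GenotypeMatrix, SiteKey


def random_matrix(rng, n_samples=100, n_sites=200, missing_rate=0.1,
                  n_chrom=2) -> GenotypeMatrix:
    """Random dosage matrix with missingness spread over a few sequences."""
    dosages = rng.choice([0, 1, 2], size=(n_samples, n_sites)).astype(np.int8)
    dosages[rng.random(dosages.shape) < missing_rate] = MISSING
    per = max(1, n_sites // n_chrom)
    sites = []
    for j in range(n_sites):
        chrom = min(j // per, n_chrom - 1)
        pos = (j - chrom * per + 1) * 10
        sites.append(SiteKey(f"chr{chrom + 1}", pos, "A", "G"))
    samples = [f"s{i:03d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, sites, dosages)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
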