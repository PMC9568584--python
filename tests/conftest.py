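import numpy as np
import pandas as pd
import pytest

from eprskit.genotypes import GenotypeMatrix


def make_matrix(dosage, chrom=None, pos=None, ref="A", alt="G", ids=None):
    """GenotypeMatrix from a plain dosage array (subjects x variants)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else [100 * (j + 1) for j in range(m)],
            "ref": [ref] * m,
            "alt": [alt] * m,
        }
    )
    return GenotypeMatrix(
        subjects=[f"S{i}" for i in range(n)], variants=variants, dosage=dosage
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """100 subjects x 12 independent variants, some missing calls."""
    dosage = rng.binomial(2, 0.3, size=(100, 12)).astype(float)
    miss = rng.random(dosage.shape) < 0.05
    dosage[miss] = np.nan
    return make_matrix(dosage)
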