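import numpy as np
import pandas as pd
import pytest

from polyscore.dataio import GenotypeCohort


def make_cohort(dosage, pos=None, chrom=None, ids=None, counted="A", other="G"):
    """Build a GenotypeCohort from a dense dosage array with default metadata."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "id": ids if ids is not None else [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "allele_counted": [counted] * m if isinstance(counted, str) else counted,
            "allele_other": [other] * m if isinstance(other, str) else other,
        }
    )
    return GenotypeCohort(dosage, variants, [f"s{i}" for i in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_cohort(rng):
    """20 samples x 50 independent variants with a few missing calls."""
    freqs = rng.uniform(0.1, 0.9, size=50)
    dosage = rng.binomial(2, freqs, size=(20, 50)).astype(float)
    miss = rng.random(dosage.shape) < 0.03
    dosage[miss] = np.nan
    return make_cohort(dosage)
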