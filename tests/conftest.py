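import numpy as np
import pandas as pd
import pytest

from igluscore.cohort_io import GenotypeMatrix


def make_matrix(dosages, phenotype, chrom="chr1", start_pos=100, ids=None):
    """Small GenotypeMatrix from a (variants x samples) dosage array."""
    d = np.asarray(dosages, dtype=np.int8)
    n_var, n_samp = d.shape
    chroms = [chrom] * n_var if isinstance(chrom, str) else list(chrom)
    variants = pd.DataFrame({
        "chrom": chroms,
        "pos": [start_pos + 10 * i for i in range(n_var)],
        "id": ids if ids is not None else [f"v{i}" for i in range(n_var)],
        "ref": ["A"] * n_var,
        "alt": ["T"] * n_var,
    })
    samples = [f"s{j}" for j in range(n_samp)]
    return GenotypeMatrix(samples, np.asarray(phenotype, dtype=object), variants, d)


@pytest.fixture
def two_group_matrix():
    """4 cases / 4 controls, one case-enriched variant and one null variant."""
    dosages = [
        [2, 2, 1, 1, 0, 0, 0, 1],  # enriched in cases
        [1, 0, 1, 0, 1, 0, 1, 0],  # balanced
    ]
    phenotype = ["case"] * 4 + ["control"] * 4
    return make_matrix(dosages, phenotype)
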