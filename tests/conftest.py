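import numpy as np
import pandas as pd
import pytest

from rohid.core import GenotypeDataset, VARIANT_COLUMNS


def make_dataset(genotypes, positions=None, chroms=None, freqs=None, sample_ids=None):
    """Build a GenotypeDataset from raw arrays (test helper)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    positions = np.arange(1, m + 1) * 10_000 if positions is None else np.asarray(positions)
    chroms = ["1"] * m if chroms is None else [str(c) for c in chroms]
    sample_ids = [f"s{i + 1}" for i in range(n)] if sample_ids is None else list(sample_ids)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j + 1}" for j in range(m)],
            "chrom": chroms,
            "pos": positions.astype(np.int64),
            "allele_a": "A",
            "allele_b": "B",
            "freq_b": np.nan if freqs is None else np.asarray(freqs, float),
        }
    )[VARIANT_COLUMNS]
    samples = pd.DataFrame({"sample_id": sample_ids})
    data = GenotypeDataset(genotypes, variants, samples)
    return data if freqs is not None else data.with_computed_frequencies()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def dataset_factory():
    return make_dataset
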