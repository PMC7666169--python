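"""Shared generators for randomized ROH test instances."""

import numpy as np

from conftest import make_dataset


def random_roh_instance(rng, max_snps=2000, n_samples=1):
    """Random genotype instance with mixed HBD-like content.

    Sizes are drawn log-uniform so most instances are small; genotype rows
    mix a noisy heterozygous background with planted homozygous blocks
    (occasionally corrupted by isolated hets/missing calls) and sporadic
    large inter-SNP gaps to exercise the gap rule.
    """
    n = int(10 ** rng.uniform(np.log10(40), np.log10(max_snps)))
    gaps = rng.integers(2_000, 15_000, n).astype(np.int64)
    big = rng.random(n) < 0.01  # occasional gaps beyond the 1 Mb split rule
    gaps[big] = rng.integers(800_000, 2_000_000, int(big.sum()))
    pos = np.cumsum(gaps)

    geno = np.zeros((n_samples, n), dtype=np.int8)
    for row in range(n_samples):
        het_rate = rng.uniform(0.2, 0.5)
        g = rng.choice([0, 1, 2], size=n, p=[(1 - het_rate) / 2, het_rate, (1 - het_rate) / 2])
        for _ in range(rng.integers(0, 4)):
            start = rng.integers(0, n)
            length = int(rng.integers(10, max(11, n // 2)))
            block = slice(start, min(n, start + length))
            g[block] = rng.choice([0, 2], size=block.stop - block.start)
            # sprinkle imperfections inside the block
            k = block.stop - block.start
            flip = rng.random(k) < 0.02
            g[block][flip] = 1
        miss = rng.random(n) < rng.uniform(0, 0.05)
        g[miss] = -1
        geno[row] = g
    return make_dataset(geno, positions=pos)
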