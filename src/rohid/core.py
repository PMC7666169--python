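"""Core data containers shared by every stage.

Genotypes are held as an int8 matrix of B-allele counts (0/1/2) with -1 for
missing calls. Positions are 1-based inclusive throughout the package; BED
exports are converted to 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

AUTOSOMES = tuple(str(c) for c in range(1, 23))

#: PLINK-convention autosomal genome length used as the default F_ROH denominator.
GENOME_LENGTH_BP = 3_000_000_000

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "allele_a", "allele_b", "freq_b"]


@dataclass
class GenotypeDataset:
    """Sample-by-variant genotype matrix plus variant and sample metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_variants)`` int8 array of B-allele counts;
        ``-1`` encodes a missing call.
    variants
        One row per variant with columns ``variant_id, chrom, pos,
        allele_a, allele_b, freq_b``. Positions are 1-based and strictly
        increasing within each chromosome.
    samples
        One row per sample; must contain a unique ``sample_id`` column.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x variants)")
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(
                f"sample table has {len(self.samples)} rows for {n} genotype rows"
            )
        if len(self.variants) != m:
            raise ValueError(
                f"variant table has {len(self.variants)} rows for {m} genotype columns"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes restricted to {0,1,2,-1}")
        if not self.samples["sample_id"].is_unique:
            raise ValueError("sample_id values must be unique")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant B-allele frequency, ignoring missing genotypes.

        Monomorphic-by-missingness columns (no non-missing call) yield NaN.
        """
        g = self.genotypes
        mask = g != MISSING
        counts = np.where(mask, g, 0).sum(axis=0).astype(float)
        denom = 2.0 * mask.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)

    def with_computed_frequencies(self) -> "GenotypeDataset":
        """Return a copy whose ``freq_b`` column is recomputed from the data."""
        variants = self.variants.copy()
        variants["freq_b"] = self.allele_frequencies()
        return GenotypeDataset(self.genotypes.copy(), variants, self.samples.copy())

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeDataset":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        variant_idx = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeDataset(
            self.genotypes[np.ix_(sample_idx, variant_idx)],
            self.variants.iloc[variant_idx].reset_index(drop=True),
            self.samples.iloc[sample_idx].reset_index(drop=True),
        )


@dataclass(frozen=True, order=True)
class ROHSegment:
    """One called run of homozygosity (1-based inclusive coordinates)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    snp_first: str = field(default="", compare=False)
    snp_last: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError("segment end before start")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def segments_to_frame(segments) -> pd.DataFrame:
    """Tabulate ROH segments (``sample_id, chrom, start_bp, end_bp, n_snps``)."""
    rows = [
        (s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_kb)
        for s in segments
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]
    )


def normalize_chrom(label) -> str:
    """Normalize a chromosome label to bare '1'..'22' / 'X' / ... form."""
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    return s
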