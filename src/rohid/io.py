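"""Genotype file formats and cohort quality control.

PLINK 1 binary (.bed/.bim/.fam, SNP-major) and VCF 4.2 (GT only) are
supported. The counted B allele is the .bim allele-1 column (PLINK A1) for
PLINK input, and ALT for VCF input.

QC applies, in order: sample call-rate filter, then variant missingness,
minor-allele-frequency and exact Hardy-Weinberg filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AUTOSOMES, MISSING, GenotypeDataset, VARIANT_COLUMNS, normalize_chrom

logger = logging.getLogger(__name__)

PLINK_MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR = 0x01

# 2-bit PLINK codes -> B-allele (=A1) counts
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Raised for malformed genotype files."""


def write_plink(data: GenotypeDataset, path_prefix) -> None:
    """Write a .bed/.bim/.fam triple (SNP-major, B allele as A1)."""
    prefix = Path(path_prefix)
    n, m = data.genotypes.shape
    bim = data.variants
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, v in bim.iterrows():
            fh.write(
                f"{v['chrom']}\t{v['variant_id']}\t0\t{v['pos']}\t{v['allele_b']}\t{v['allele_a']}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for _, s in data.samples.iterrows():
            sex_code = {"male": 1, "female": 2}.get(str(s.get("sex", "")), 0)
            fh.write(f"{s['sample_id']}\t{s['sample_id']}\t0\t0\t{sex_code}\t-9\n")
    n_bytes = math.ceil(n / 4)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC + bytes([SNP_MAJOR]))
        for j in range(m):
            col = data.genotypes[:, j]
            buf = bytearray(n_bytes)
            for i in range(n):
                buf[i >> 2] |= _BED_ENCODE[int(col[i])] << ((i & 3) * 2)
            fh.write(bytes(buf))


def read_plink(path_prefix) -> GenotypeDataset:
    """Read a PLINK 1 .bed/.bim/.fam triple into a genotype dataset."""
    prefix = Path(path_prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "sample_id", "father", "mother", "sex_code", "phenotype"],
        dtype={"sample_id": str, "fid": str},
    )
    if len(fam) == 0:
        raise FormatError(f"{prefix.with_suffix('.fam')} has no samples")
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "allele_b", "allele_a"],
        dtype={"chrom": str, "variant_id": str, "allele_b": str, "allele_a": str},
    )
    if len(bim) == 0:
        raise FormatError(f"{prefix.with_suffix('.bim')} has no variants")
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != PLINK_MAGIC:
        raise FormatError("bad .bed magic bytes")
    if raw[2] != SNP_MAJOR:
        raise FormatError("only SNP-major .bed files are supported")
    n, m = len(fam), len(bim)
    n_bytes = math.ceil(n / 4)
    if len(raw) - 3 != n_bytes * m:
        raise FormatError(
            f".bed payload is {len(raw) - 3} bytes; expected {n_bytes * m} "
            f"for {n} samples x {m} variants"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (body[:, :, None] >> shifts) & 0b11  # (m, n_bytes, 4)
    geno = _BED_DECODE[two_bit.reshape(m, -1)[:, :n]].T.copy()

    sex = fam["sex_code"].map({1: "male", 2: "female"})
    samples = pd.DataFrame({"sample_id": fam["sample_id"], "sex": sex})
    variants = pd.DataFrame(
        {
            "variant_id": bim["variant_id"],
            "chrom": bim["chrom"].map(normalize_chrom),
            "pos": bim["pos"].astype(np.int64),
            "allele_a": bim["allele_a"],
            "allele_b": bim["allele_b"],
            "freq_b": np.nan,
        }
    )
    data = GenotypeDataset(geno, variants[VARIANT_COLUMNS], samples)
    return data.with_computed_frequencies()


def read_vcf(path) -> GenotypeDataset:
    """Read biallelic records of a VCF 4.x with a GT field.

    ALT is the counted B allele; ``./.`` becomes missing; multiallelic
    records are skipped (counted in the log).
    """
    from cyvcf2 import VCF

    reader = VCF(str(path), gts012=True)
    if "##FORMAT=<ID=GT" not in reader.raw_header:
        raise FormatError("VCF has no GT format field")
    rows = []
    geno_cols = []
    skipped = 0
    for v in reader:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        geno_cols.append(gt)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append((vid, normalize_chrom(v.CHROM), v.POS, v.REF, v.ALT[0], np.nan))
    if skipped:
        logger.warning("skipped %d non-biallelic VCF records", skipped)
    if not rows:
        raise FormatError(f"no usable biallelic records in {path}")
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    samples = pd.DataFrame({"sample_id": list(reader.samples)})
    data = GenotypeDataset(np.column_stack(geno_cols), variants, samples)
    return data.with_computed_frequencies()


def write_vcf(data: GenotypeDataset, path) -> None:
    """Write genotypes as a minimal VCF 4.2 with GT only (B allele = ALT)."""
    chrom_max = data.variants.groupby("chrom", sort=False)["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohid\n")
        for chrom, length in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={int(length) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.sample_ids)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, v in data.variants.iterrows():
            calls = "\t".join(gt_strings[int(g)] for g in data.genotypes[:, j])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['allele_a']}\t"
                f"{v['allele_b']}\t.\t.\t.\tGT\t{calls}\n"
            )


def read_phenotypes(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in table.columns:
        raise FormatError("phenotype table must have a sample_id column")
    return table


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, no mid-p).

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, that are no more likely than the observed one.
    """
    obs_homr = min(n_hom1, n_hom2)
    obs_homc = max(n_hom1, n_hom2)
    n = n_het + obs_homr + obs_homc
    if n == 0:
        return 1.0
    rare = 2 * obs_homr + n_het
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    probs[mid] = 1.0
    het, homr, homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het > 1:
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (homr + 1) * (homc + 1))
        het -= 2
        homr += 1
        homc += 1
    het, homr, homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while het <= rare - 2:
        probs[het + 2] = probs[het] * 4.0 * homr * homc / ((het + 2.0) * (het + 1.0))
        het += 2
        homr -= 1
        homc -= 1
    total = probs.sum()
    target = probs[n_het]
    return float(min(1.0, probs[probs <= target * (1 + 1e-12)].sum() / total))


@dataclass
class QCThresholds:
    """Cohort QC cutoffs: variant missingness > 0.01, MAF < 0.01 and HWE
    exact p < 5e-4 remove variants; sample missingness > 0.02 removes
    samples first."""

    variant_missing_max: float = 0.01
    maf_min: float = 0.01
    hwe_p_min: float = 5.0e-4
    sample_missing_max: float = 0.02


@dataclass
class QCReport:
    n_samples_in: int = 0
    n_variants_in: int = 0
    samples_removed_missing: int = 0
    variants_removed_non_autosomal: int = 0
    variants_removed_missing: int = 0
    variants_removed_maf: int = 0
    variants_removed_hwe: int = 0
    n_samples_out: int = 0
    n_variants_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v) for k, v in self.__dict__.items()], columns=["rule", "count"]
        )


def qc_filter(
    data: GenotypeDataset, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypeDataset, QCReport]:
    """Apply cohort QC; returns the filtered dataset and a removal report.

    Order of application: non-autosomal variant drop, sample call-rate
    filter, then the three variant filters evaluated on the remaining
    samples.
    """
    if data.n_samples == 0 or data.n_variants == 0:
        raise ValueError("empty dataset")
    report = QCReport(n_samples_in=data.n_samples, n_variants_in=data.n_variants)

    chrom = data.variants["chrom"].map(normalize_chrom)
    autosomal = chrom.isin(AUTOSOMES).to_numpy()
    report.variants_removed_non_autosomal = int((~autosomal).sum())
    if report.variants_removed_non_autosomal:
        logger.warning("removed %d non-autosomal variants", report.variants_removed_non_autosomal)
        data = data.subset(variant_idx=np.flatnonzero(autosomal))

    g = data.genotypes
    sample_missing = (g == MISSING).mean(axis=1)
    keep_samples = sample_missing <= thresholds.sample_missing_max
    report.samples_removed_missing = int((~keep_samples).sum())
    data = data.subset(sample_idx=np.flatnonzero(keep_samples))
    if data.n_samples == 0:
        raise ValueError("all samples removed by the call-rate filter")

    g = data.genotypes
    observed = g != MISSING
    variant_missing = 1.0 - observed.mean(axis=0)
    keep = variant_missing <= thresholds.variant_missing_max
    report.variants_removed_missing = int((~keep).sum())

    freqs = data.allele_frequencies()
    maf = np.minimum(freqs, 1.0 - freqs)
    maf_fail = ~(maf >= thresholds.maf_min)  # NaN frequency also fails
    report.variants_removed_maf = int((maf_fail & keep).sum())
    keep &= ~maf_fail

    hwe_fail = np.zeros(data.n_variants, dtype=bool)
    for j in np.flatnonzero(keep):
        col = g[:, j]
        n_het = int((col == 1).sum())
        n_hom_a = int((col == 0).sum())
        n_hom_b = int((col == 2).sum())
        if hwe_exact_pvalue(n_het, n_hom_a, n_hom_b) < thresholds.hwe_p_min:
            hwe_fail[j] = True
    report.variants_removed_hwe = int(hwe_fail.sum())
    keep &= ~hwe_fail

    if not keep.any():
        raise ValueError(f"all variants removed by QC: {report}")
    data = data.subset(variant_idx=np.flatnonzero(keep)).with_computed_frequencies()
    report.n_samples_out = data.n_samples
    report.n_variants_out = data.n_variants
    return data, report


def drop_related(
    data: GenotypeDataset, kinship: pd.DataFrame, pihat_max: float = 0.8
) -> GenotypeDataset:
    """Drop one sample of each pair with PIHAT above the cutoff.

    ``kinship`` is a precomputed pairwise table with columns
    ``sample_a, sample_b, pihat``; IBD estimation itself is out of scope.
    """
    flagged = kinship[kinship["pihat"] > pihat_max]
    drop = set()
    for _, row in flagged.iterrows():
        if row["sample_a"] in drop or row["sample_b"] in drop:
            continue
        drop.add(row["sample_b"])
    if drop:
        logger.warning("dropping %d samples from high-PIHAT pairs", len(drop))
    keep = [i for i, sid in enumerate(data.sample_ids) if sid not in drop]
    return data.subset(sample_idx=np.array(keep))
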