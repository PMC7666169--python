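"""Genomic inbreeding coefficients, the GRM, and genotype PCs.

Three per-sample coefficients are provided:

* ``F_ROH`` — summed length of ROH above a threshold (default > 1.5 Mb,
  strict) over the autosomal genome length (default 3 Gb);
* ``F_GRM`` — the correlation-between-uniting-gametes estimator
  (PLINK ``--ibc`` Fhat3) computed from common loci (MAF > 0.05):
  ``(1/N) sum_i (x_i^2 - (1+2 p_i) x_i + 2 p_i^2) / (2 p_i (1-p_i))``;
* ``F_outsideROH`` — excess homozygosity restricted to SNPs outside the
  sample's called ROH: ``(O' - E') / (N' - E')`` with
  ``O' = O(HOM) - N_SNP_ROH``, ``E' = ((N - N_ROH)/N) E(HOM)``,
  ``N' = N - N_ROH`` and ``E(HOM) = sum_i (1 - 2 p_i (1 - p_i))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GENOME_LENGTH_BP, MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

F_ROH_THRESHOLD_MB = 1.5


@dataclass
class HomozygosityCounts:
    """Per-sample ingredients of the outside-ROH excess-homozygosity statistic."""

    o_hom: float
    e_hom: float
    n: int
    n_snp_roh: float
    n_roh: int


def compute_f_roh(
    segments,
    sample_ids,
    genome_length_bp: float = GENOME_LENGTH_BP,
    threshold_mb: float = F_ROH_THRESHOLD_MB,
) -> pd.Series:
    """F_ROH = sum of ROH strictly longer than ``threshold_mb`` / genome length.

    Samples without qualifying segments get 0.
    """
    if genome_length_bp <= 0:
        raise ValueError("genome length must be positive")
    totals = dict.fromkeys(sample_ids, 0.0)
    cutoff = threshold_mb * 1_000_000.0
    for s in segments:
        if s.length_bp < 0:
            raise ValueError("negative segment length")
        if s.length_bp > cutoff and s.sample_id in totals:
            totals[s.sample_id] += s.length_bp
    return pd.Series(totals, name="F_ROH").reindex(list(sample_ids)) / genome_length_bp


def roh_summaries(segments, sample_ids, threshold_mb: float = F_ROH_THRESHOLD_MB) -> pd.DataFrame:
    """Per-sample count and summed kb of qualifying ROH (> threshold)."""
    n_roh = dict.fromkeys(sample_ids, 0)
    sum_kb = dict.fromkeys(sample_ids, 0.0)
    cutoff = threshold_mb * 1_000_000.0
    for s in segments:
        if s.length_bp > cutoff and s.sample_id in n_roh:
            n_roh[s.sample_id] += 1
            sum_kb[s.sample_id] += s.length_kb
    return pd.DataFrame({"n_roh": pd.Series(n_roh), "sum_roh_kb": pd.Series(sum_kb)}).reindex(
        list(sample_ids)
    )


def _common_loci_mask(freqs: np.ndarray, maf_min: float) -> np.ndarray:
    maf = np.minimum(freqs, 1.0 - freqs)
    return np.isfinite(freqs) & (maf > maf_min)


def _resolve_freqs(data: GenotypeDataset, freqs) -> np.ndarray:
    """Frequencies to use: explicit argument > variant-table freq_b > data."""
    if freqs is not None:
        return np.asarray(freqs, dtype=float)
    table = data.variants["freq_b"].to_numpy(dtype=float)
    if np.isfinite(table).any():
        return table
    return data.allele_frequencies()


def compute_f_grm(
    data: GenotypeDataset,
    freqs: np.ndarray | None = None,
    maf_min: float = 0.05,
) -> pd.Series:
    """Fhat3 per sample over common loci, averaging over non-missing genotypes."""
    freqs = _resolve_freqs(data, freqs)
    keep = _common_loci_mask(freqs, maf_min)
    if not keep.any():
        raise ValueError("no loci left after the MAF filter")
    p = freqs[keep]
    x = data.genotypes[:, keep].astype(float)
    observed = x != MISSING
    x[~observed] = 0.0
    denom_locus = 2.0 * p * (1.0 - p)
    term = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom_locus
    term[~observed] = 0.0
    n_used = observed.sum(axis=1)
    if np.any(n_used == 0):
        raise ValueError("a sample has zero usable loci after the MAF filter")
    values = term.sum(axis=1) / n_used
    return pd.Series(values, index=data.sample_ids, name="F_GRM")


def roh_membership(data: GenotypeDataset, segments) -> np.ndarray:
    """Boolean (samples x variants) matrix: SNP position inside any called
    segment of that sample, boundaries inclusive."""
    inside = np.zeros(data.genotypes.shape, dtype=bool)
    chrom_arr = data.variants["chrom"].to_numpy()
    pos_arr = data.variants["pos"].to_numpy()
    chrom_index = {}
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        chrom_index[str(chrom)] = (idx, pos_arr[idx])
    row_of = {sid: i for i, sid in enumerate(data.sample_ids)}
    for s in segments:
        if s.chrom not in chrom_index or s.sample_id not in row_of:
            continue
        idx, pos = chrom_index[s.chrom]
        lo = np.searchsorted(pos, s.start_bp, side="left")
        hi = np.searchsorted(pos, s.end_bp, side="right")
        if hi > lo:
            inside[row_of[s.sample_id], idx[lo:hi]] = True
    return inside


def homozygosity_counts(
    data: GenotypeDataset, segments, freqs: np.ndarray | None = None
) -> list[HomozygosityCounts]:
    """Per-sample observed/expected homozygosity split by ROH membership."""
    freqs = _resolve_freqs(data, freqs)
    usable = np.isfinite(freqs)
    g = data.genotypes
    observed = (g != MISSING) & usable
    hom = ((g == 0) | (g == 2)) & observed
    e_locus = 1.0 - 2.0 * freqs * (1.0 - freqs)
    inside = roh_membership(data, segments)
    counts = []
    for row in range(data.n_samples):
        obs = observed[row]
        counts.append(
            HomozygosityCounts(
                o_hom=float(hom[row].sum()),
                e_hom=float(e_locus[obs].sum()),
                n=int(obs.sum()),
                n_snp_roh=float((hom[row] & inside[row]).sum()),
                n_roh=int((obs & inside[row]).sum()),
            )
        )
    return counts


def compute_f_outside_roh(
    data: GenotypeDataset, segments, freqs: np.ndarray | None = None
) -> pd.Series:
    """Excess homozygosity outside called ROH; NaN where the denominator
    degenerates (N' = E'). With no segments this reduces to the classic
    (O - E)/(N - E) coefficient."""
    values = []
    for c in homozygosity_counts(data, segments, freqs):
        o_prime = c.o_hom - c.n_snp_roh
        e_prime = ((c.n - c.n_roh) / c.n) * c.e_hom if c.n else np.nan
        n_prime = c.n - c.n_roh
        denom = n_prime - e_prime
        if not np.isfinite(denom) or abs(denom) < 1e-12:
            logger.warning("degenerate F_outsideROH denominator; flagged as NaN")
            values.append(np.nan)
        else:
            values.append((o_prime - e_prime) / denom)
    return pd.Series(values, index=data.sample_ids, name="F_outsideROH")


def compute_grm(
    data: GenotypeDataset,
    freqs: np.ndarray | None = None,
    maf_min: float = 0.05,
) -> np.ndarray:
    """Frequency-standardized GRM with per-pair denominators for missingness.

    ``A_jk = (1/N_jk) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``
    over loci where both samples are genotyped; monomorphic loci excluded.
    """
    if data.n_samples < 2:
        raise ValueError("GRM requires at least two samples")
    freqs = _resolve_freqs(data, freqs)
    keep = _common_loci_mask(freqs, maf_min)
    if not keep.any():
        raise ValueError("no polymorphic loci for the GRM")
    p = freqs[keep]
    x = data.genotypes[:, keep].astype(float)
    observed = x != MISSING
    x[~observed] = 0.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    z = np.where(observed, (x - 2.0 * p) / scale, 0.0)
    pair_n = observed.astype(float) @ observed.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (z @ z.T) / pair_n
    a[pair_n == 0] = 0.0
    return (a + a.T) / 2.0


def ld_prune(
    data: GenotypeDataset,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy pairwise-r2 pruning; returns indices of retained variants.

    Mirrors the usual windowed heuristic (window SNPs, sliding by ``step``,
    drop the later SNP of any pair with r2 above the cutoff).
    """
    g = data.genotypes.astype(float)
    g[g == MISSING] = np.nan
    m = data.n_variants
    keep = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        idx = [i for i in range(start, min(start + window, m)) if keep[i]]
        for a_pos in range(len(idx)):
            if not keep[idx[a_pos]]:
                continue
            for b_pos in range(a_pos + 1, len(idx)):
                i, j = idx[a_pos], idx[b_pos]
                if not keep[j]:
                    continue
                xi, xj = g[:, i], g[:, j]
                ok = np.isfinite(xi) & np.isfinite(xj)
                if ok.sum() < 3:
                    continue
                vi, vj = xi[ok], xj[ok]
                if vi.std() == 0 or vj.std() == 0:
                    continue
                r = np.corrcoef(vi, vj)[0, 1]
                if r * r > r2_max:
                    keep[j] = False
        start += step
    return np.flatnonzero(keep)


def compute_pcs(
    data: GenotypeDataset,
    k: int = 15,
    maf_min: float = 0.05,
    prune: bool = True,
) -> pd.DataFrame:
    """Top-k principal components from the GRM.

    Coordinates are eigenvectors scaled by the root eigenvalue; each PC's
    largest-magnitude loading is made positive so runs are bit-identical.
    """
    if k > data.n_samples:
        raise ValueError("k exceeds the number of samples")
    if k == 0:
        return pd.DataFrame(index=data.sample_ids)
    work = data
    if prune and data.n_variants > 1:
        kept = ld_prune(data)
        if len(kept) >= 2:
            work = data.subset(variant_idx=kept)
    a = compute_grm(work, maf_min=maf_min)
    eigvals, eigvecs = np.linalg.eigh(a)
    order = np.argsort(eigvals)[::-1][:k]
    coords = eigvecs[:, order] * np.sqrt(np.maximum(eigvals[order], 0.0))
    for j in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, j]))
        if coords[pivot, j] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords, index=data.sample_ids, columns=[f"pc{i + 1}" for i in range(coords.shape[1])]
    )


def inbreeding_profile(
    data: GenotypeDataset,
    segments,
    genome_length_bp: float = GENOME_LENGTH_BP,
    threshold_mb: float = F_ROH_THRESHOLD_MB,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Assemble the per-sample exposure table used by every ID regression."""
    sample_ids = data.sample_ids
    out = pd.DataFrame(index=sample_ids)
    out["F_ROH"] = compute_f_roh(segments, sample_ids, genome_length_bp, threshold_mb)
    out["F_GRM"] = compute_f_grm(data, maf_min=maf_min)
    out["F_outsideROH"] = compute_f_outside_roh(data, segments)
    out = out.join(roh_summaries(segments, sample_ids, threshold_mb))
    out.index.name = "sample_id"
    return out
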