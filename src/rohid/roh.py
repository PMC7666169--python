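"""Sliding-window detection of runs of homozygosity.

The algorithm, per sample and chromosome:

1. slide a window of ``window_snps`` consecutive SNPs; a window is
   homozygous if it holds at most ``window_max_het`` heterozygous and
   ``window_max_missing`` missing calls;
2. each SNP's hit fraction is the share of windows covering it that are
   homozygous (near chromosome ends the denominator is the number of
   windows that actually exist); the SNP is in homozygous state when the
   fraction reaches ``window_hit_threshold``;
3. maximal stretches of in-state SNPs are split wherever the gap between
   adjacent SNPs exceeds ``max_gap_kb``;
4. stretches passing the SNP-count, length and density floors are emitted,
   bounded by the positions of their first and last SNP.

No linkage-disequilibrium pruning is applied. :func:`brute_force_roh`
re-executes the same four steps with literal per-SNP window enumeration and
exists purely as a test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeDataset, ROHSegment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    """Calling parameters; defaults follow the PLINK ``--homozyg`` set
    (snp 30, kb 300, density 30, gap 1000, window-snp 30, window-het 1,
    window-missing 5, window-threshold 0.05)."""

    min_snps: int = 30
    min_length_kb: float = 300.0
    max_density_kb_per_snp: float = 30.0
    max_gap_kb: float = 1000.0
    window_snps: int = 30
    window_max_het: int = 1
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_snps", "window_snps", "window_max_het", "window_max_missing"):
            if getattr(self, name) < 0 or (name in ("min_snps", "window_snps") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must lie in (0, 1]")
        if self.min_length_kb < 0 or self.max_density_kb_per_snp <= 0 or self.max_gap_kb <= 0:
            raise ValueError("length/density/gap parameters must be positive")


def _emit_stretches(
    in_state: np.ndarray,
    pos: np.ndarray,
    snp_ids,
    sample_id: str,
    chrom: str,
    params: ROHParams,
) -> list[ROHSegment]:
    """Steps 3-4: split in-state stretches at large gaps and filter."""
    gap_bp = params.max_gap_kb * 1000.0
    segments = []
    n = len(pos)
    i = 0
    while i < n:
        if not in_state[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and in_state[j + 1]
            and (pos[j + 1] - pos[j]) <= gap_bp
        ):
            j += 1
        n_snps = j - i + 1
        length_bp = int(pos[j] - pos[i] + 1)
        length_kb = length_bp / 1000.0
        if (
            n_snps >= params.min_snps
            and length_kb >= params.min_length_kb
            and length_kb / n_snps <= params.max_density_kb_per_snp
        ):
            segments.append(
                ROHSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start_bp=int(pos[i]),
                    end_bp=int(pos[j]),
                    n_snps=n_snps,
                    snp_first=str(snp_ids[i]),
                    snp_last=str(snp_ids[j]),
                )
            )
        i = j + 1
    return segments


def _in_state_vectorized(g: np.ndarray, params: ROHParams) -> np.ndarray | None:
    """Steps 1-2 for one sample/chromosome; None if too few SNPs."""
    n = len(g)
    w = params.window_snps
    if n < w:
        return None
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    cs_het = np.concatenate(([0], np.cumsum(het)))
    cs_mis = np.concatenate(([0], np.cumsum(mis)))
    win_het = cs_het[w:] - cs_het[:-w]
    win_mis = cs_mis[w:] - cs_mis[:-w]
    hom_win = (win_het <= params.window_max_het) & (win_mis <= params.window_max_missing)
    n_win = n - w + 1
    cs_hom = np.concatenate(([0], np.cumsum(hom_win.astype(np.int64))))
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    denom = hi - lo + 1
    hits = cs_hom[hi + 1] - cs_hom[lo]
    return hits / denom >= params.window_hit_threshold


def call_roh(data: GenotypeDataset, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Call ROH segments for every sample (vectorized implementation).

    Variants must be sorted by (chromosome, position); chromosomes with
    fewer SNPs than one window are skipped with a warning.
    """
    chrom_arr = data.variants["chrom"].to_numpy()
    pos_arr = data.variants["pos"].to_numpy()
    id_arr = data.variants["variant_id"].to_numpy()
    segments: list[ROHSegment] = []
    skipped = set()
    for chrom in pd.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[cols]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        if len(cols) < params.window_snps:
            skipped.add(str(chrom))
            continue
        ids = id_arr[cols]
        for row, sample_id in enumerate(data.sample_ids):
            in_state = _in_state_vectorized(data.genotypes[row, cols], params)
            segments.extend(
                _emit_stretches(in_state, pos, ids, sample_id, str(chrom), params)
            )
    for chrom in sorted(skipped):
        logger.warning(
            "chromosome %s has fewer SNPs than one window (%d); skipped",
            chrom,
            params.window_snps,
        )
    return segments


def brute_force_roh(
    data: GenotypeDataset, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    """Literal re-execution of the four calling steps (test oracle only).

    Enumerates every window covering every SNP with plain loops; intended
    for small inputs, no performance contract.
    """
    w = params.window_snps
    segments: list[ROHSegment] = []
    for chrom in pd.unique(data.variants["chrom"].to_numpy()):
        sub = data.variants[data.variants["chrom"] == chrom]
        cols = sub.index.to_list()
        pos = sub["pos"].to_list()
        ids = sub["variant_id"].to_list()
        n = len(cols)
        if n < w:
            continue
        for row, sample_id in enumerate(data.sample_ids):
            g = [int(data.genotypes[row, c]) for c in cols]
            window_hom = []
            for j in range(n - w + 1):
                hets = 0
                missing = 0
                for k in range(j, j + w):
                    if g[k] == 1:
                        hets += 1
                    elif g[k] == MISSING:
                        missing += 1
                window_hom.append(
                    hets <= params.window_max_het
                    and missing <= params.window_max_missing
                )
            in_state = []
            for i in range(n):
                covering = [
                    window_hom[j]
                    for j in range(len(window_hom))
                    if j <= i <= j + w - 1
                ]
                frac = sum(covering) / len(covering)
                in_state.append(frac >= params.window_hit_threshold)
            segments.extend(
                _emit_stretches(
                    np.asarray(in_state),
                    np.asarray(pos),
                    ids,
                    sample_id,
                    str(chrom),
                    params,
                )
            )
    return segments


def filter_roh(segments, min_length_mb: float) -> list[ROHSegment]:
    """Keep segments strictly longer than ``min_length_mb`` megabases."""
    if min_length_mb < 0:
        raise ValueError("length threshold must be non-negative")
    cutoff_bp = min_length_mb * 1_000_000.0
    return [s for s in segments if s.length_bp > cutoff_bp]


def to_hom_table(segments) -> pd.DataFrame:
    """PLINK ``.hom``-compatible table of called segments."""
    rows = [
        (
            s.sample_id,
            s.sample_id,
            s.chrom,
            s.snp_first,
            s.snp_last,
            s.start_bp,
            s.end_bp,
            round(s.length_kb, 3),
            s.n_snps,
            round(s.length_kb / s.n_snps, 4),
        )
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=["FID", "IID", "CHR", "SNP1", "SNP2", "POS1", "POS2", "KB", "NSNP", "DENSITY"],
    )


def to_bed_table(segments) -> pd.DataFrame:
    """Segments as 0-based half-open BED records."""
    rows = [(s.chrom, s.start_bp - 1, s.end_bp, s.sample_id) for s in segments]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
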