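"""Synthetic cohorts with known autozygosity and directional dominance.

The generator plants homozygous-by-descent (HBD) segments at a controlled
per-individual inbreeding level, emits Hardy-Weinberg genotypes elsewhere,
and builds quantitative traits from a locus-level additive + dominance
model, so that every downstream estimate can be checked against truth.

Trait model per individual::

    y = M0 + sum_i g_i + covariates + polygenic + residual

with locus genotypic values ``-a, d_i, +a`` for B-allele counts 0, 1, 2.
The expected change of the mean under inbreeding level F is the closed form
``-2 F sum_i d_i p_i q_i`` exposed by :func:`expected_depression`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeDataset, VARIANT_COLUMNS

SEX_LEVELS = ("male", "female")


def draw_from_law(law, size, rng: np.random.Generator) -> np.ndarray:
    """Sample from a distribution spec tuple.

    Supported laws: ``("point", v)``, ``("uniform", lo, hi)``,
    ``("exponential", mean)``, ``("beta", a, b)``.
    """
    kind = law[0]
    if kind == "point":
        return np.full(size, float(law[1]))
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size)
    if kind == "exponential":
        return rng.exponential(law[1], size)
    if kind == "beta":
        return rng.beta(law[1], law[2], size)
    raise ValueError(f"unknown distribution law {law!r}")


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort."""

    n_individuals: int
    chromosome_lengths: Sequence[int]
    snp_spacing_bp: float = 10_000.0
    allele_freq_law: tuple = ("uniform", 0.05, 0.5)
    f_target_law: tuple = ("point", 0.0)
    hbd_length_law: tuple = ("exponential", 3_000_000.0)
    n_causal_loci: int = 0
    additive_effect_a: float = 0.0
    dominance_mean_d: float = 0.0
    dominance_sd_d: float = 0.0
    causal_maf_range: tuple = (0.05, 0.5)
    covariate_effects: dict = field(default_factory=dict)
    sex_specific_beta: tuple | None = None
    polygenic_variance: float = 0.0
    residual_variance: float = 1.0
    trait_mean: float = 0.0
    missing_rate: float = 0.0
    n_sites: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) == 0:
            raise ValueError("at least one chromosome is required")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.f_target_law[0] == "point" and not 0.0 <= self.f_target_law[1] < 1.0:
            raise ValueError("target inbreeding coefficient must lie in [0, 1)")
        if self.f_target_law[0] == "uniform" and not (
            0.0 <= self.f_target_law[1] and self.f_target_law[2] < 1.0
        ):
            raise ValueError("f_target_law support must lie within [0, 1)")
        if self.residual_variance < 0 or self.polygenic_variance < 0:
            raise ValueError("variances must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def genome_length_bp(self) -> int:
        return int(sum(self.chromosome_lengths))

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, salt)))


@dataclass
class TrueHBDSet:
    """Ground-truth autozygous intervals per sample (1-based inclusive)."""

    segments: pd.DataFrame  # sample_id, chrom, start_bp, end_bp
    f_true: pd.Series  # indexed by sample_id
    genome_length_bp: int

    def sample_intervals(self, sample_id: str, chrom: str) -> list[tuple[int, int]]:
        sub = self.segments
        sub = sub[(sub["sample_id"] == sample_id) & (sub["chrom"] == chrom)]
        return list(zip(sub["start_bp"], sub["end_bp"]))


@dataclass
class TraitArchitecture:
    """Resolved causal-locus parameters of one simulated trait."""

    causal_idx: np.ndarray  # indices into the variant table
    p: np.ndarray  # B-allele frequencies of causal loci
    d: np.ndarray  # per-locus dominance deviations
    a: float  # shared additive half-difference


def simulate_variants(config: SimConfig) -> pd.DataFrame:
    """Place variants on each chromosome at roughly even spacing.

    Returns a variant table (1-based positions, strictly increasing per
    chromosome) with ``freq_b`` drawn from ``config.allele_freq_law``.
    """
    rng = config.rng(salt=1)
    rows = []
    for ci, length in enumerate(config.chromosome_lengths, start=1):
        n = int(length // config.snp_spacing_bp)
        if n == 0:
            continue
        grid = (np.arange(n) + 0.5) * config.snp_spacing_bp
        jitter = rng.uniform(-0.4, 0.4, n) * config.snp_spacing_bp
        pos = np.maximum(1, np.round(grid + jitter)).astype(np.int64)
        pos = np.maximum.accumulate(pos)  # guard rounding collisions
        pos += np.arange(n)  # strictly increasing even after accumulate ties
        pos = np.minimum(pos, int(length))
        # final pass: enforce strict increase within the chromosome bound
        for k in range(1, n):
            if pos[k] <= pos[k - 1]:
                pos[k] = pos[k - 1] + 1
        chrom = str(ci)
        for k in range(n):
            rows.append((f"snp_{chrom}_{k + 1}", chrom, int(pos[k])))
    if not rows:
        raise ValueError("no variants could be placed; check spacing vs lengths")
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])
    variants["allele_a"] = "A"
    variants["allele_b"] = "B"
    variants["freq_b"] = np.clip(
        draw_from_law(config.allele_freq_law, len(variants), rng), 1e-6, 1 - 1e-6
    )
    return variants[VARIANT_COLUMNS]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + 1:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def simulate_hbd(config: SimConfig, variants: pd.DataFrame | None = None) -> TrueHBDSet:
    """Plant HBD segments per sample until the target genome fraction is met.

    Greedy accumulation: segment lengths come from ``hbd_length_law``,
    placement is uniform, overlaps merge. The final segment is truncated to
    the remaining target so realized F_true tracks the target closely; any
    residual shortfall from merging is accepted and recorded in F_true.
    """
    rng = config.rng(salt=2)
    lengths = np.asarray(config.chromosome_lengths, dtype=np.int64)
    genome = int(lengths.sum())
    chrom_prob = lengths / lengths.sum()
    targets = draw_from_law(config.f_target_law, config.n_individuals, rng)
    if np.any(targets >= 1.0) or np.any(targets < 0.0):
        raise ValueError("target inbreeding coefficients must lie in [0, 1)")

    rows = []
    f_true = {}
    for i in range(config.n_individuals):
        sample_id = f"ind_{i + 1}"
        target_bp = targets[i] * genome
        per_chrom: dict[int, list[tuple[int, int]]] = {}
        covered = 0
        while covered < target_bp:
            seg_len = max(1, int(draw_from_law(config.hbd_length_law, 1, rng)[0]))
            remaining = int(math.ceil(target_bp - covered))
            seg_len = min(seg_len, remaining) if remaining >= 1 else seg_len
            ci = int(rng.choice(len(lengths), p=chrom_prob))
            chrom_len = int(lengths[ci])
            seg_len = min(seg_len, chrom_len)
            start = int(rng.integers(1, chrom_len - seg_len + 2))
            end = start + seg_len - 1
            per_chrom.setdefault(ci, []).append((start, end))
            per_chrom[ci] = _merge_intervals(per_chrom[ci])
            covered = sum(
                e - s + 1 for ivs in per_chrom.values() for s, e in ivs
            )
        f_true[sample_id] = covered / genome
        for ci, ivs in sorted(per_chrom.items()):
            for start, end in ivs:
                rows.append((sample_id, str(ci + 1), start, end))

    segments = pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp", "end_bp"])
    order = [f"ind_{i + 1}" for i in range(config.n_individuals)]
    return TrueHBDSet(segments, pd.Series(f_true).reindex(order), genome)


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Sample table mirroring the cohort covariate structure.

    sex Bernoulli(0.5); age uniform 40-60; categorical site with a per-site
    night-light scalar in [0, 63]; SES quintile 1-5; edu 1-4; occu 1-5.
    """
    rng = config.rng(salt=3)
    n = config.n_individuals
    site_ids = [f"site_{j + 1}" for j in range(config.n_sites)]
    # half the sites below the luminosity-5 cutoff, half above
    low = rng.integers(0, 5, (config.n_sites + 1) // 2)
    high = rng.integers(5, 64, config.n_sites // 2)
    site_light = dict(zip(site_ids, np.concatenate([low, high]).astype(int)))
    site = rng.choice(site_ids, n)
    return pd.DataFrame(
        {
            "sample_id": [f"ind_{i + 1}" for i in range(n)],
            "sex": rng.choice(SEX_LEVELS, n),
            "age": rng.uniform(40, 60, n),
            "site": site,
            "SES.Q": rng.integers(1, 6, n),
            "edu": rng.integers(1, 5, n),
            "occu": rng.integers(1, 6, n),
            "night_light": np.array([site_light[s] for s in site]),
        }
    )


def simulate_genotypes(
    variants: pd.DataFrame, hbd: TrueHBDSet, config: SimConfig
) -> GenotypeDataset:
    """Emit genotypes: homozygous-by-frequency inside HBD, HWE outside."""
    rng = config.rng(salt=4)
    n = config.n_individuals
    p = variants["freq_b"].to_numpy()
    m = len(variants)

    geno = rng.binomial(2, p, size=(n, m)).astype(np.int8)

    # overwrite HBD intervals with autozygous (homozygous) draws
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    chrom_slices = {}
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        chrom_slices[chrom] = (idx, pos_arr[idx])

    sample_ids = [f"ind_{i + 1}" for i in range(n)]
    sample_row = {sid: i for i, sid in enumerate(sample_ids)}
    for _, seg in hbd.segments.iterrows():
        if seg["chrom"] not in chrom_slices:
            continue
        idx, pos = chrom_slices[seg["chrom"]]
        lo = np.searchsorted(pos, seg["start_bp"], side="left")
        hi = np.searchsorted(pos, seg["end_bp"], side="right")
        if hi <= lo:
            continue
        cols = idx[lo:hi]
        row = sample_row[seg["sample_id"]]
        hom = (rng.random(hi - lo) < p[cols]).astype(np.int8) * 2
        geno[row, cols] = hom

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        geno[mask] = MISSING

    samples = simulate_covariates(config)
    return GenotypeDataset(geno, variants.copy(), samples)


def draw_architecture(
    variants: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> TraitArchitecture:
    """Pick causal loci within ``causal_maf_range`` and draw their d_i."""
    rng = config.rng(salt=5) if rng is None else rng
    p = variants["freq_b"].to_numpy()
    maf = np.minimum(p, 1 - p)
    lo, hi = config.causal_maf_range
    eligible = np.flatnonzero((maf >= lo) & (maf <= hi))
    if len(eligible) < config.n_causal_loci:
        raise ValueError(
            f"only {len(eligible)} loci in causal_maf_range for "
            f"{config.n_causal_loci} requested causal loci"
        )
    causal = np.sort(rng.choice(eligible, config.n_causal_loci, replace=False))
    if config.dominance_sd_d > 0:
        d = rng.normal(config.dominance_mean_d, config.dominance_sd_d, len(causal))
    else:
        d = np.full(len(causal), float(config.dominance_mean_d))
    return TraitArchitecture(causal, p[causal], d, config.additive_effect_a)


def simulate_trait(
    genotypes: GenotypeDataset,
    config: SimConfig,
    covariates: pd.DataFrame | None = None,
    architecture: TraitArchitecture | None = None,
    f_true: pd.Series | None = None,
    grm: np.ndarray | None = None,
) -> tuple[pd.Series, TraitArchitecture]:
    """Build a trait from genotypic values, covariates and noise.

    With ``sex_specific_beta`` set, locus-level dominance is replaced by a
    direct ``beta_sex * F_true`` term (requires ``f_true``). Passing ``grm``
    correlates the polygenic term through that matrix; the default is an
    independent normal per sample.
    """
    rng = config.rng(salt=6)
    covariates = genotypes.samples if covariates is None else covariates
    n = genotypes.n_samples

    if architecture is None:
        architecture = draw_architecture(genotypes.variants, config, rng)

    y = np.full(n, float(config.trait_mean))

    use_dominance = config.sex_specific_beta is None
    if len(architecture.causal_idx) > 0:
        g = genotypes.genotypes[:, architecture.causal_idx].astype(float)
        g[g == MISSING] = np.nan
        value = architecture.a * (g - 1.0)  # -a / 0 / +a for counts 0/1/2
        if use_dominance:
            het = g == 1.0
            value = np.where(het, architecture.d, value)
        y += np.nansum(value, axis=1)

    if config.sex_specific_beta is not None:
        if f_true is None:
            raise ValueError("sex_specific_beta requires f_true")
        beta_male, beta_female = config.sex_specific_beta
        sex = covariates["sex"].to_numpy()
        f = f_true.reindex(covariates["sample_id"]).to_numpy()
        y += np.where(sex == "male", beta_male, beta_female) * f

    for name, effect in config.covariate_effects.items():
        y += effect * pd.to_numeric(covariates[name]).to_numpy()

    if config.polygenic_variance > 0:
        u = rng.normal(0.0, math.sqrt(config.polygenic_variance), n)
        if grm is not None:
            a = np.asarray(grm, dtype=float)
            a = a + np.eye(n) * 1e-6 * max(1.0, np.trace(a) / n)
            chol = np.linalg.cholesky(a)
            z = rng.standard_normal(n)
            u = math.sqrt(config.polygenic_variance) * (chol @ z) / math.sqrt(
                max(np.mean(np.diag(a)), 1e-12)
            )
        y += u

    if config.residual_variance > 0:
        y += rng.normal(0.0, math.sqrt(config.residual_variance), n)

    trait = pd.Series(y, index=covariates["sample_id"].to_numpy(), name="trait")
    return trait, architecture


def expected_depression(architecture: TraitArchitecture, f: float) -> float:
    """Closed-form mean trait change at inbreeding level ``f``: -2F sum d p q."""
    p = architecture.p
    return float(-2.0 * f * np.sum(architecture.d * p * (1.0 - p)))
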