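"""End-to-end orchestration: simulate/load -> QC -> ROH -> inbreeding
metrics -> ID models -> regional scan, from a single config dict.

Every stage is a pure function of (inputs, config, seed); the manifest
written next to the outputs records parameters and row counts so a rerun
with the same config is bit-identical for deterministic stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from . import metrics, models, synthetic, windows
from .core import GENOME_LENGTH_BP
from .roh import ROHParams, call_roh, filter_roh, to_hom_table

logger = logging.getLogger(__name__)

DEFAULT_LUMINOSITY_CUTOFF = 5.0


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derivation from the single pipeline seed."""
    import zlib

    return int(
        np.random.SeedSequence((seed, zlib.crc32(stage.encode()))).generate_state(1)[0]
    )


def _sim_config_from_dict(cfg: dict, seed: int) -> synthetic.SimConfig:
    fields = dict(cfg)
    fields.setdefault("seed", seed)
    for key in ("allele_freq_law", "f_target_law", "hbd_length_law", "causal_maf_range"):
        if key in fields and isinstance(fields[key], list):
            fields[key] = tuple(fields[key])
    if "sex_specific_beta" in fields and isinstance(fields["sex_specific_beta"], list):
        fields["sex_specific_beta"] = tuple(fields["sex_specific_beta"])
    return synthetic.SimConfig(**fields)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all stages per the config; returns the result bundle.

    Config keys (all optional unless noted): ``seed``; either ``simulate``
    (SimConfig fields) or ``plink_prefix``/``vcf`` plus ``phenotypes``;
    ``qc`` (QCThresholds fields); ``roh`` (ROHParams fields);
    ``froh_threshold_mb``; ``genome_length_bp``; ``traits`` (list);
    ``strata`` (subset of {sex, luminosity}); ``luminosity_cutoff``;
    ``window_width_bp``; ``use_grm`` (bool); ``n_pcs``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": {}}

    # ---- stage: acquire genotypes + phenotypes -------------------------
    if "simulate" in config:
        sim_cfg = _sim_config_from_dict(config["simulate"], derive_seed(seed, "simulate"))
        variants = synthetic.simulate_variants(sim_cfg)
        hbd = synthetic.simulate_hbd(sim_cfg, variants)
        data = synthetic.simulate_genotypes(variants, hbd, sim_cfg)
        trait, arch = synthetic.simulate_trait(data, sim_cfg, f_true=hbd.f_true)
        data.samples["trait"] = trait.to_numpy()
        truth = pd.DataFrame({"sample_id": hbd.f_true.index, "F_true": hbd.f_true.to_numpy()})
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
        hbd.segments.to_csv(out_dir / "truth_segments.tsv", sep="\t", index=False)
        chromosome_lengths = list(sim_cfg.chromosome_lengths)
        manifest["stages"]["simulate"] = {
            "n_individuals": sim_cfg.n_individuals,
            "n_variants": data.n_variants,
            "mean_f_true": float(hbd.f_true.mean()),
        }
    else:
        if "plink_prefix" in config:
            data = gio.read_plink(config["plink_prefix"])
        elif "vcf" in config:
            data = gio.read_vcf(config["vcf"])
        else:
            raise ValueError("config needs 'simulate', 'plink_prefix' or 'vcf'")
        pheno_path = config.get("phenotypes")
        if pheno_path:
            if not Path(pheno_path).exists():
                raise FileNotFoundError(f"phenotype file not found: {pheno_path}")
            pheno = gio.read_phenotypes(pheno_path)
            data.samples = data.samples.merge(pheno, on="sample_id", how="left", suffixes=("", "_pheno"))
        chromosome_lengths = (
            data.variants.groupby("chrom", sort=False)["pos"].max().astype(int).tolist()
        )
        manifest["stages"]["load"] = {"n_samples": data.n_samples, "n_variants": data.n_variants}

    # ---- stage: QC -----------------------------------------------------
    data, qc_report = gio.qc_filter(data, gio.QCThresholds(**config.get("qc", {})))
    qc_report.to_frame().to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    manifest["stages"]["qc"] = {
        "n_samples": data.n_samples,
        "n_variants": data.n_variants,
    }

    # ---- stage: ROH calling -------------------------------------------
    roh_params = ROHParams(**config.get("roh", {}))
    segments = call_roh(data, roh_params)
    to_hom_table(segments).to_csv(out_dir / "roh.hom.tsv", sep="\t", index=False)
    manifest["stages"]["roh"] = {"n_segments": len(segments), "params": asdict(roh_params)}

    # ---- stage: inbreeding metrics ------------------------------------
    froh_threshold = float(config.get("froh_threshold_mb", metrics.F_ROH_THRESHOLD_MB))
    genome_length = float(config.get("genome_length_bp", GENOME_LENGTH_BP))
    profile = metrics.inbreeding_profile(
        data, segments, genome_length_bp=genome_length, threshold_mb=froh_threshold
    )
    profile.to_csv(out_dir / "inbreeding_profile.tsv", sep="\t")
    n_pcs = int(config.get("n_pcs", 0))
    if n_pcs > 0:
        pcs = metrics.compute_pcs(data, k=n_pcs)
        data.samples = data.samples.join(pcs.reset_index(drop=True))
        pcs.to_csv(out_dir / "pcs.tsv", sep="\t")
    manifest["stages"]["inbreeding"] = {
        "mean_F_ROH": float(profile["F_ROH"].mean()),
        "froh_threshold_mb": froh_threshold,
    }

    # ---- stage: ID models ---------------------------------------------
    grm = metrics.compute_grm(data) if config.get("use_grm") else None
    traits = config.get("traits", ["trait"])
    strata = config.get("strata", [])
    luminosity_cutoff = float(config.get("luminosity_cutoff", DEFAULT_LUMINOSITY_CUTOFF))
    estimates = []
    covariates = config.get("covariates", {})
    for trait in traits:
        spec = (
            models.CovariateModelSpec(trait, list(covariates[trait]))
            if trait in covariates
            else models.CovariateModelSpec(trait, _default_available_covariates(trait, data.samples))
        )
        estimates.append(
            models.two_step_estimate(trait, data.samples, profile, grm=grm, spec=spec)
        )
        for group in strata:
            estimates.extend(
                models.fit_stratified(
                    trait,
                    data.samples,
                    profile,
                    grm=grm,
                    strata=group,
                    luminosity_cutoff=luminosity_cutoff,
                    spec=spec,
                )
            )
    results = models.estimates_to_frame(estimates)
    alpha_traits = 0.05 / max(len(traits), 1)
    results["significant"] = results["p"] < alpha_traits
    results.to_csv(out_dir / "id_estimates.tsv", sep="\t", index=False)
    manifest["stages"]["id_models"] = {
        "n_estimates": len(results),
        "alpha_per_trait": alpha_traits,
    }

    # ---- stage: regional scan -----------------------------------------
    width = int(config.get("window_width_bp", windows.WINDOW_WIDTH_BP))
    wins = windows.make_windows(chromosome_lengths, width=width)
    qualifying = filter_roh(segments, froh_threshold)
    fracs = windows.window_roh_fraction(qualifying, wins, data.sample_ids)
    trait0 = traits[0]
    y, x, kept = models.build_design(
        trait0,
        data.samples,
        models.CovariateModelSpec(trait0, _default_available_covariates(trait0, data.samples)),
    )
    import statsmodels.api as sm

    residuals = np.asarray(sm.OLS(y, x).fit().resid, dtype=float)
    kept_ids = data.samples.loc[kept, "sample_id"].tolist()
    scan_results = windows.scan(residuals, fracs.loc[kept_ids], windows=wins)
    scan_results.to_csv(out_dir / "window_scan.tsv", sep="\t", index=False)
    tested_p = scan_results.loc[scan_results["tested"], "p"]
    if len(tested_p):
        windows.qq_points(tested_p.clip(lower=1e-300)).to_csv(
            out_dir / "qq_points.tsv", sep="\t", index=False
        )
    manifest["stages"]["scan"] = {
        "n_windows": len(wins),
        "n_tested": int(scan_results["tested"].sum()),
        "bonferroni_threshold": scan_results.attrs.get("bonferroni_threshold"),
    }

    manifest["config"] = _jsonable(config)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "data": data,
        "segments": segments,
        "profile": profile,
        "estimates": results,
        "scan": scan_results,
        "manifest": manifest,
        "out_dir": out_dir,
    }


def _default_available_covariates(trait: str, samples: pd.DataFrame) -> list[str]:
    """Default covariate list for a trait, restricted to available columns."""
    wanted = models.DEFAULT_TRAIT_MODELS.get(
        trait, ["sex", "age", "SES.Q", "night_light"]
    )
    available = []
    for cov in wanted:
        col = "age" if cov == "age2" else cov
        if col in samples.columns:
            available.append(cov)
    return available


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def summarize(bundle: dict) -> str:
    """Human-readable per-trait / per-stratum effect table plus scan recap."""
    results: pd.DataFrame = bundle["estimates"]
    lines = ["trait\tstratum\tbeta_std\tp\tsignificant"]
    for _, row in results.iterrows():
        star = "*" if row.get("significant", False) else ""
        lines.append(
            f"{row['trait']}\t{row['stratum']}\t{row['beta_std']:.4g}\t{row['p']:.3g}\t{star}"
        )
    scan_results = bundle.get("scan")
    if scan_results is not None:
        n_sig = int(scan_results["significant"].sum())
        lines.append("")
        lines.append(
            f"regional scan: {int(scan_results['tested'].sum())} windows tested, "
            f"{n_sig} significant at threshold "
            f"{scan_results.attrs.get('bonferroni_threshold', float('nan')):.3g}"
        )
    return "\n".join(lines)
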