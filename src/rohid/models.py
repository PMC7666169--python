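"""Inbreeding-depression regression machinery.

Two-step estimation: (1) remove fixed covariates and the polygenic
background from the trait with a single-GRM mixed model, keeping the
residuals; (2) regress those residuals on the inbreeding coefficients
(F_ROH, optionally F_outsideROH, or the bivariate F_ROH + F_GRM pair) by
ordinary least squares. Stratified variants re-run the full pipeline per
stratum and standardize effects with the within-stratum trait SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: pedigree inbreeding coefficient of a second-cousin mating's offspring
SECOND_COUSIN_F = 1.0 / 64.0

#: family-wise error control across the trait panel
N_TRAITS_BONFERRONI = 14

CATEGORICAL_COVARIATES = {"sex", "site", "edu", "occu", "SES.Q"}

_PCS = [f"pc{i}" for i in range(1, 16)]

#: per-trait fixed-covariate lists of the cohort analysis
DEFAULT_TRAIT_MODELS: dict[str, list[str]] = {
    "SES.Q": ["sex", "age", "edu", "occu", "night_light", *_PCS],
    **{
        t: ["sex", "age", "age2", "SES.Q", "night_light", *_PCS]
        for t in ("height", "weight", "BMI", "HDL", "LDL", "TC", "TG")
    },
    **{
        t: ["sex", "age", "age2", "height", "SES.Q", "night_light", *_PCS]
        for t in ("WHR", "VAT", "SCAT")
    },
    **{
        t: ["sex", "age", "age2", "SES.Q", "BMI", "night_light", *_PCS]
        for t in ("pulse", "systolic_bp", "diastolic_bp")
    },
}


@dataclass
class CovariateModelSpec:
    """Trait name plus the fixed covariates entering step 1."""

    trait: str
    covariates: list[str] = field(default_factory=list)

    @classmethod
    def default_for(cls, trait: str) -> "CovariateModelSpec":
        if trait not in DEFAULT_TRAIT_MODELS:
            raise KeyError(f"no default covariate model for trait {trait!r}")
        return cls(trait, list(DEFAULT_TRAIT_MODELS[trait]))


@dataclass
class PolygenicFit:
    """Step-1 mixed-model fit."""

    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    residuals: np.ndarray  # y - Xb - BLUP(u)
    loglik: float
    unidentifiable: bool = False
    columns: list[str] = field(default_factory=list)


@dataclass
class IDEstimate:
    """One fitted inbreeding-depression effect."""

    trait: str
    stratum: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    beta_standardized: float
    n: int


@dataclass
class BivariateIDEstimate:
    trait: str
    beta_froh: float
    se_froh: float
    p_froh: float
    beta_fgrm: float
    se_fgrm: float
    p_fgrm: float
    n: int


def build_design(
    trait: str, samples: pd.DataFrame, spec: CovariateModelSpec | None = None
) -> tuple[np.ndarray, pd.DataFrame, pd.Index]:
    """Response vector and fixed-effect design matrix for one trait.

    Categorical covariates expand to treatment-coded indicators, ``age2``
    is the square of centered age, and an intercept column is included.
    Rows with missing values in any used column are dropped (logged).
    Returns ``(y, X, kept_row_index)``.
    """
    spec = CovariateModelSpec.default_for(trait) if spec is None else spec
    needed = {trait}
    for cov in spec.covariates:
        needed.add("age" if cov == "age2" else cov)
    missing_cols = sorted(c for c in needed if c not in samples.columns)
    if missing_cols:
        raise KeyError(f"unknown column(s) in sample table: {missing_cols}")

    usable = samples[sorted(needed)].notna().all(axis=1)
    if not usable.all():
        logger.info("build_design(%s): dropped %d rows with missing values", trait, (~usable).sum())
    sub = samples.loc[usable]
    if len(sub) == 0:
        raise ValueError("empty design after dropping rows with missing values")

    y = pd.to_numeric(sub[trait]).to_numpy(float)
    cols = {}
    for cov in spec.covariates:
        if cov == "age2":
            age = pd.to_numeric(sub["age"]).to_numpy(float)
            cols["age2"] = (age - age.mean()) ** 2  # centered for conditioning
        elif cov in CATEGORICAL_COVARIATES:
            dummies = pd.get_dummies(sub[cov].astype("category"), prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols[str(name)] = dummies[name].to_numpy(float)
        else:
            cols[cov] = pd.to_numeric(sub[cov]).to_numpy(float)
    x = pd.DataFrame(cols, index=sub.index)
    x.insert(0, "intercept", 1.0)
    return y, x, sub.index


def _reml_neg2_loglik(delta: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray) -> tuple[float, dict]:
    """Profiled -2 REML log-likelihood at variance ratio delta = sg2/se2."""
    v = delta * d + 1.0
    w = 1.0 / v
    xtw = xt * w[:, None]
    xtx = xt.T @ xtw
    xty = xtw.T @ yt
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("X'V^-1X is singular in the REML fit") from exc
    r = yt - xt @ beta
    q = float(r @ (w * r))
    n, p = xt.shape
    sigma_e2 = q / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X is not positive definite")
    neg2 = (n - p) * math.log(sigma_e2) + float(np.sum(np.log(v))) + logdet_xtx + (n - p)
    aux = {"beta": beta, "sigma_e2": sigma_e2, "resid_t": r, "w": w}
    return neg2, aux


def fit_polygenic(y: np.ndarray, x, a: np.ndarray) -> PolygenicFit:
    """REML fit of ``y = Xb + u + e`` with ``u ~ N(0, sigma_g^2 A)``.

    Uses one spectral decomposition of A and a bounded scalar search over
    the variance ratio (tolerance 1e-6). Residuals subtract both the fixed
    effects and the BLUP of u. When A is (numerically) the identity the
    split of variance is unidentifiable: the fit is flagged, reported at
    the ``sigma_g^2 = 0`` boundary, and the residuals equal OLS residuals.
    """
    columns = list(x.columns) if hasattr(x, "columns") else []
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    n = len(y)
    if a.shape != (n, n):
        raise ValueError("GRM dimensions do not match the response")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")

    eigvals, u = np.linalg.eigh((a + a.T) / 2.0)
    if eigvals.min() < -1e-6 * max(1.0, abs(eigvals.max())):
        a_reg = a + np.eye(n) * (abs(eigvals.min()) + 1e-8)
        eigvals, u = np.linalg.eigh((a_reg + a_reg.T) / 2.0)
        if eigvals.min() < 0 and eigvals.min() < -1e-8:
            raise np.linalg.LinAlgError("GRM not positive semi-definite after regularization")
    eigvals = np.maximum(eigvals, 0.0)

    yt = u.T @ y
    xt = u.T @ x

    spread = eigvals.max() - eigvals.min()
    unidentifiable = spread < 1e-8 * max(1.0, eigvals.max())
    if unidentifiable:
        delta = 0.0
        logger.warning("GRM has no eigenvalue spread; variance split unidentifiable, "
                       "reporting the sigma_g^2 = 0 boundary")
    else:
        result = optimize.minimize_scalar(
            lambda ld: _reml_neg2_loglik(math.exp(ld), eigvals, yt, xt)[0],
            bounds=(math.log(1e-8), math.log(1e8)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        delta = math.exp(result.x)
        # snap to the boundary when the optimum sits at the edge
        null_neg2, _ = _reml_neg2_loglik(1e-12, eigvals, yt, xt)
        if null_neg2 <= result.fun + 1e-9:
            delta = 0.0

    neg2, aux = _reml_neg2_loglik(max(delta, 1e-12), eigvals, yt, xt)
    beta = aux["beta"]
    sigma_e2 = aux["sigma_e2"]
    sigma_g2 = delta * sigma_e2
    # BLUP shrinkage in the eigenbasis: u_hat_t = (delta d / (delta d + 1)) r_t
    v = delta * eigvals + 1.0
    resid_t = aux["resid_t"] / v
    residuals = u @ resid_t
    return PolygenicFit(
        beta=beta,
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        residuals=residuals,
        loglik=-0.5 * neg2,
        unidentifiable=bool(unidentifiable),
        columns=columns,
    )


def _ols_estimate(
    y: np.ndarray, x: pd.DataFrame
) -> sm.regression.linear_model.RegressionResultsWrapper:
    return sm.OLS(y, x).fit()


def fit_id(
    residuals: np.ndarray | pd.Series,
    profile: pd.DataFrame,
    include_f_outside: bool = True,
    trait_sd: float | None = None,
    trait: str = "trait",
    stratum: str = "all",
) -> IDEstimate:
    """Step-2 regression of trait residuals on F_ROH.

    ``residuals = mu + beta_FROH * F_ROH [+ beta_Fout * F_outsideROH] + e``
    by OLS (which is the ML solution for the coefficients). The
    standardized effect divides beta by ``trait_sd`` (defaults to the SD of
    the supplied residual vector).
    """
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(profile):
        raise ValueError("residuals and profile are not aligned")
    froh = profile["F_ROH"].to_numpy(float)
    if np.ptp(froh) == 0:
        raise ValueError("F_ROH has zero variance in this stratum")
    x = pd.DataFrame({"intercept": 1.0, "F_ROH": froh})
    if include_f_outside:
        fout = profile["F_outsideROH"].to_numpy(float)
        if np.ptp(fout) > 0:
            x["F_outsideROH"] = fout
    fit = _ols_estimate(residuals, x)
    beta = float(fit.params["F_ROH"])
    se = float(fit.bse["F_ROH"])
    ci = fit.conf_int(alpha=0.05).loc["F_ROH"]
    sd = float(np.std(residuals, ddof=1)) if trait_sd is None else float(trait_sd)
    return IDEstimate(
        trait=trait,
        stratum=stratum,
        beta=beta,
        se=se,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["F_ROH"]),
        beta_standardized=beta / sd if sd > 0 else np.nan,
        n=len(residuals),
    )


def fit_bivariate(
    residuals: np.ndarray | pd.Series,
    profile: pd.DataFrame,
    trait: str = "trait",
    cond_max: float = 1e8,
) -> BivariateIDEstimate:
    """Joint OLS on F_ROH and F_GRM; both conditional coefficients reported."""
    residuals = np.asarray(residuals, dtype=float)
    froh = profile["F_ROH"].to_numpy(float)
    fgrm = profile["F_GRM"].to_numpy(float)
    if np.ptp(froh) == 0 or np.ptp(fgrm) == 0:
        raise ValueError("an inbreeding coefficient has zero variance")
    z = np.column_stack([(froh - froh.mean()) / froh.std(), (fgrm - fgrm.mean()) / fgrm.std()])
    if np.linalg.cond(z) > cond_max:
        raise ValueError(
            "F_ROH and F_GRM are collinear beyond the condition-number guard; "
            "fit univariate models instead"
        )
    x = pd.DataFrame({"intercept": 1.0, "F_ROH": froh, "F_GRM": fgrm})
    fit = _ols_estimate(residuals, x)
    return BivariateIDEstimate(
        trait=trait,
        beta_froh=float(fit.params["F_ROH"]),
        se_froh=float(fit.bse["F_ROH"]),
        p_froh=float(fit.pvalues["F_ROH"]),
        beta_fgrm=float(fit.params["F_GRM"]),
        se_fgrm=float(fit.bse["F_GRM"]),
        p_fgrm=float(fit.pvalues["F_GRM"]),
        n=len(residuals),
    )


def two_step_estimate(
    trait: str,
    samples: pd.DataFrame,
    profile: pd.DataFrame,
    grm: np.ndarray | None = None,
    spec: CovariateModelSpec | None = None,
    include_f_outside: bool = True,
    stratum: str = "all",
) -> IDEstimate:
    """Full two-step fit for one trait on one (sub)cohort.

    ``samples`` must carry ``sample_id``; ``profile`` is indexed by
    sample_id. Without a GRM, step 1 degenerates to OLS covariate removal.
    """
    y, x, kept = build_design(trait, samples, spec)
    sample_ids = samples.loc[kept, "sample_id"].to_numpy()
    if grm is None:
        fit1 = _ols_estimate(y, x)
        residuals = np.asarray(fit1.resid, dtype=float)
    else:
        rows = samples.index.get_indexer(kept)
        fit1 = fit_polygenic(y, x, np.asarray(grm)[np.ix_(rows, rows)])
        residuals = fit1.residuals
    prof = profile.loc[sample_ids]
    return fit_id(
        residuals,
        prof,
        include_f_outside=include_f_outside,
        trait_sd=float(np.std(y, ddof=1)),
        trait=trait,
        stratum=stratum,
    )


def fit_stratified(
    trait: str,
    samples: pd.DataFrame,
    profile: pd.DataFrame,
    grm: np.ndarray | None = None,
    strata: str = "sex",
    luminosity_cutoff: float = 5.0,
    spec: CovariateModelSpec | None = None,
    include_f_outside: bool = True,
    min_stratum_size: int = 50,
) -> list[IDEstimate]:
    """Two-step fit per stratum (sex, or night-light below/above cutoff).

    For luminosity strata the night-light covariate is removed and the
    sampling site added instead. Standardization uses the within-stratum
    trait SD. Undersized strata are skipped with a warning.
    """
    spec = CovariateModelSpec.default_for(trait) if spec is None else spec
    if strata == "sex":
        groups = {s: samples[samples["sex"] == s] for s in ("male", "female")}
        group_spec = spec
    elif strata == "luminosity":
        light = pd.to_numeric(samples["night_light"])
        groups = {
            f"luminosity<{luminosity_cutoff:g}": samples[light < luminosity_cutoff],
            f"luminosity>={luminosity_cutoff:g}": samples[light >= luminosity_cutoff],
        }
        covs = [c for c in spec.covariates if c != "night_light"]
        if "site" not in covs:
            covs.append("site")
        group_spec = CovariateModelSpec(spec.trait, covs)
    else:
        raise ValueError(f"unknown stratification {strata!r}")

    estimates = []
    for label, sub in groups.items():
        if len(sub) < min_stratum_size:
            logger.warning("stratum %s has %d samples (< %d); skipped", label, len(sub), min_stratum_size)
            continue
        estimates.append(
            two_step_estimate(
                trait,
                sub.reset_index(drop=True),
                profile,
                grm=None if grm is None else _subset_grm(grm, samples, sub),
                spec=group_spec,
                include_f_outside=include_f_outside,
                stratum=label,
            )
        )
    return estimates


def _subset_grm(grm: np.ndarray, samples: pd.DataFrame, sub: pd.DataFrame) -> np.ndarray:
    pos = {sid: i for i, sid in enumerate(samples["sample_id"])}
    rows = np.array([pos[sid] for sid in sub["sample_id"]])
    return np.asarray(grm)[np.ix_(rows, rows)]


def compare_strata(
    residuals: np.ndarray | pd.Series,
    froh: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """ANCOVA-style interaction test between two strata.

    Fits ``resid = mu + beta F_ROH + gamma group + delta (F_ROH x group)``
    and returns ``(delta, p)`` — the between-group difference in the ID
    slope and its two-sided p-value.
    """
    residuals = np.asarray(residuals, dtype=float)
    froh = np.asarray(froh, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("compare_strata needs two groups")
    if len(levels) > 2:
        raise ValueError("compare_strata supports exactly two groups")
    ind = (group == levels[1]).astype(float)
    x = pd.DataFrame(
        {"intercept": 1.0, "F_ROH": froh, "group": ind, "interaction": froh * ind}
    )
    fit = _ols_estimate(residuals, x)
    return float(fit.params["interaction"]), float(fit.pvalues["interaction"])


def compare_beta_sets(betas_a, betas_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two sets of standardized effects.

    Exact null distribution when both sets have at most 20 values and no
    ties straddle the sets; normal approximation with tie correction
    otherwise.
    """
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each set needs at least two values")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def predicted_change(estimate: IDEstimate, f: float = SECOND_COUSIN_F) -> float:
    """Mean trait change for offspring at inbreeding level ``f``: beta * f."""
    return estimate.beta * f


def estimates_to_frame(estimates) -> pd.DataFrame:
    rows = [
        (
            e.trait,
            e.stratum,
            e.beta,
            e.se,
            e.ci_low,
            e.ci_high,
            e.p_value,
            e.beta_standardized,
            e.n,
        )
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=["trait", "stratum", "beta", "se", "ci_low", "ci_high", "p", "beta_std", "n"],
    )
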