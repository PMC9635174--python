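"""Synthetic two-cohort generator with known latent-module structure.

The generator emulates the statistical structure of a paired discovery /
validation multi-omics study: log-normal raw abundances whose log2 values load
on shared latent factors, detection-limit (left-censoring) missingness for
metabolites, blind duplicate specimens with per-analyte measurement noise,
clinical traits coupled to chosen factors, and Weibull proportional-hazards
survival driven by selected factor scores plus clinical covariates.

The discovery covariate profile mimics an elderly general-population cohort
(mean age ~76, eGFR ~65, ~23% deaths over ~6.6 years of follow-up); the
validation profile mimics a middle-aged CKD trial cohort (mean age ~54,
measured GFR ~46, all participants on antihypertensives, no diabetes, 24 h
urine protein instead of ACR, and a positive age-GFR coupling induced by the
GFR-based enrolment window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import AnalyteMatrix, CohortBundle, OmodError

_LN2 = math.log(2.0)


@dataclass
class CovariateProfile:
    """Marginal distributions of the clinical covariates for one cohort."""

    n_samples: int = 1000
    age_mean: float = 75.7
    age_sd: float = 5.2
    female_p: float = 0.538
    gfr_mean: float = 65.0
    gfr_sd: float = 18.0
    chol_mean: float = 179.0
    chol_sd: float = 41.7
    hdl_mean: float = 51.2
    hdl_sd: float = 13.8
    sbp_mean: float = 130.2
    sbp_sd: float = 18.0
    bmi_mean: float = 28.7
    bmi_sd: float = 5.5
    glucose_mean: float = 114.0
    glucose_sd: float = 28.7
    cvd_p: float = 0.186
    smoking_p: float = 0.5
    diabetes_p: float = 0.297
    antihyp_p: float = 0.672
    urine_col: str = "acr"  # "acr" (mg/g) or "upro24" (mg/day)
    log2_urine_mean: float = math.log2(11.0)
    log2_urine_sd: float = 1.44
    centers: tuple[str, ...] | None = ("FC", "JK", "MN", "WC")
    center_probs: tuple[float, ...] | None = (0.3, 0.25, 0.25, 0.2)
    age_gfr_corr: float = 0.0
    censor_low: float = 5.2
    censor_high: float = 8.0
    hazard_multiplier: float = 1.0


#: CKD-trial-like validation cohort (shifted covariates, same factor structure)
VALIDATION_PROFILE = CovariateProfile(
    n_samples=700,
    age_mean=54.5,
    age_sd=10.7,
    female_p=0.385,
    gfr_mean=46.0,
    gfr_sd=13.0,
    chol_mean=212.0,
    chol_sd=45.9,
    hdl_mean=48.2,
    hdl_sd=16.0,
    sbp_mean=150.9,
    sbp_sd=23.8,
    bmi_mean=30.5,
    bmi_sd=6.4,
    glucose_mean=94.2,
    glucose_sd=15.4,
    cvd_p=0.507,
    smoking_p=0.5,
    diabetes_p=0.0,
    antihyp_p=1.0,
    urine_col="upro24",
    log2_urine_mean=math.log2(109.0),
    log2_urine_sd=2.8,
    centers=None,
    center_probs=None,
    age_gfr_corr=0.5,
    censor_low=7.0,
    censor_high=10.5,
    hazard_multiplier=1.5,
)


@dataclass
class SimDesign:
    """Shared generative design for a discovery/validation cohort pair.

    ``loadings`` gives the per-factor loading magnitude lambda; by default
    factors span [0.5, 0.95] evenly so modules differ in coherence (as real
    modules do).  A float produces a uniform panel.  On the log2 scale each
    analyte is ``lambda * Z_factor + Normal(0, noise_sd)``, so the within-
    module correlation is lambda^2 / (lambda^2 + noise_sd^2).
    """

    n_factors: int = 20
    proteins_per_factor: int = 10
    metabolites_per_factor: int = 5
    loadings: float | tuple[float, ...] | None = None
    noise_sd: float = 0.6
    n_background_proteins: int = 30
    n_background_metabolites: int = 10
    xenobiotic_fraction: float = 0.10
    detection_limit_quantile: float = 0.05
    heavy_missing_fraction: float = 0.05
    heavy_missing_quantile: float = 0.85
    n_duplicate_pairs: int = 50
    duplicate_cv: float = 0.08
    high_cv_fraction: float = 0.05
    high_cv_value: float = 0.8
    # trait -> (factor index, correlation)
    trait_couplings: dict = field(
        default_factory=lambda: {
            "gfr": (0, -0.8),
            "sex": (1, 0.6),
            "glucose": (2, 0.6),
            "log2_urine": (0, 0.4),
        }
    )
    # factor index -> per-SD log hazard
    survival_betas: dict = field(default_factory=lambda: {3: 0.33, 4: -0.30})
    # covariate -> log hazard per unit (continuous covariates centred at the
    # discovery profile mean so the baseline rate is interpretable)
    covariate_log_hazards: dict = field(
        default_factory=lambda: {
            "age": 0.06,
            "sex": -0.3,
            "gfr": -0.015,
            "cvd": 0.4,
            "smoking": 0.3,
            "diabetes": 0.3,
        }
    )
    weibull_shape: float = 1.0
    baseline_rate: float = 0.029  # per year; ~23% events under the defaults
    profile: CovariateProfile = field(default_factory=CovariateProfile)
    validation_profile: CovariateProfile = field(
        default_factory=lambda: replace(VALIDATION_PROFILE)
    )

    def factor_loadings(self) -> np.ndarray:
        if self.loadings is None:
            return np.linspace(0.5, 0.95, self.n_factors)
        if np.isscalar(self.loadings):
            lam = np.full(self.n_factors, float(self.loadings))
        else:
            lam = np.asarray(self.loadings, dtype=float)
            if lam.shape != (self.n_factors,):
                raise OmodError("loadings must have one value per factor")
        if np.any(lam <= 0) or np.any(lam > 1):
            raise OmodError("loadings must lie in (0, 1]")
        return lam

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise OmodError("noise_sd must be positive")
        if not 0 <= self.detection_limit_quantile < 1:
            raise OmodError("detection_limit_quantile must be in [0, 1)")
        if self.proteins_per_factor + self.metabolites_per_factor < 2:
            raise OmodError("every factor needs at least 2 analytes")
        for k in self.survival_betas:
            if not 0 <= int(k) < self.n_factors:
                raise OmodError(f"survival beta references factor {k} out of range")
        for trait, (k, r) in self.trait_couplings.items():
            if not 0 <= int(k) < self.n_factors:
                raise OmodError(
                    f"trait coupling {trait!r} references factor {k} out of range"
                )
            if not -1 <= r <= 1:
                raise OmodError(f"trait coupling {trait!r} must be in [-1, 1]")
        self.factor_loadings()


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort pair."""

    factor_of_analyte: pd.Series  # -1 for background / xenobiotic analytes
    lambda_of_analyte: pd.Series
    duplicate_cv_of_analyte: pd.Series
    survival_betas: dict
    trait_couplings: dict
    factor_loadings: np.ndarray

    def analytes_of_factor(self, k: int) -> list[str]:
        return list(self.factor_of_analyte.index[self.factor_of_analyte == k])

    def to_json_dict(self) -> dict:
        return {
            "factor_of_analyte": self.factor_of_analyte.to_dict(),
            "lambda_of_analyte": self.lambda_of_analyte.to_dict(),
            "duplicate_cv_of_analyte": self.duplicate_cv_of_analyte.to_dict(),
            "survival_betas": {str(k): v for k, v in self.survival_betas.items()},
            "trait_couplings": {
                t: [int(k), float(r)] for t, (k, r) in self.trait_couplings.items()
            },
            "factor_loadings": np.asarray(self.factor_loadings).tolist(),
        }


def _build_panel(design: SimDesign, rng: np.random.Generator):
    """Analyte ids, factor map, lambdas, offsets and duplicate CVs (shared
    between the two cohorts of a pair)."""
    lam_factor = design.factor_loadings()
    ids, types, factors, lams = [], [], [], []
    p = 0
    m = 0
    for k in range(design.n_factors):
        for _ in range(design.proteins_per_factor):
            p += 1
            ids.append(f"P{p:04d}")
            types.append("protein")
            factors.append(k)
            lams.append(lam_factor[k])
        for _ in range(design.metabolites_per_factor):
            m += 1
            ids.append(f"M{m:04d}")
            types.append("metabolite")
            factors.append(k)
            lams.append(lam_factor[k])
    for _ in range(design.n_background_proteins):
        p += 1
        ids.append(f"P{p:04d}")
        types.append("protein")
        factors.append(-1)
        lams.append(0.0)
    for _ in range(design.n_background_metabolites):
        m += 1
        ids.append(f"M{m:04d}")
        types.append("metabolite")
        factors.append(-1)
        lams.append(0.0)
    n_met_base = m
    n_xeno = int(round(design.xenobiotic_fraction * n_met_base))
    xeno = [False] * len(ids)
    for _ in range(n_xeno):
        m += 1
        ids.append(f"M{m:04d}")
        types.append("metabolite")
        factors.append(-1)
        lams.append(0.0)
        xeno.append(True)

    meta = pd.DataFrame(
        {
            "analyte_type": types,
            "xenobiotic": xeno,
            "display_name": ids,
        },
        index=pd.Index(ids, name="analyte_id"),
    )
    is_protein = np.array([t == "protein" for t in types])
    offsets = np.where(
        is_protein, rng.uniform(6.0, 14.0, len(ids)), rng.uniform(-2.0, 4.0, len(ids))
    )
    # measurement CV: a small fraction of proteins are poor assays
    cvs = np.full(len(ids), design.duplicate_cv)
    protein_idx = np.flatnonzero(is_protein)
    n_high = int(round(design.high_cv_fraction * len(protein_idx)))
    if n_high:
        high = rng.choice(protein_idx, size=n_high, replace=False)
        cvs[high] = design.high_cv_value
    # metabolite detection limits: most mild, a few effectively unmeasurable
    met_idx = np.flatnonzero(~is_protein)
    dl_q = np.zeros(len(ids))
    dl_q[met_idx] = design.detection_limit_quantile
    n_heavy = int(round(design.heavy_missing_fraction * len(met_idx)))
    if n_heavy:
        heavy = rng.choice(met_idx, size=n_heavy, replace=False)
        dl_q[heavy] = design.heavy_missing_quantile
    panel = {
        "meta": meta,
        "factor": np.asarray(factors),
        "lam": np.asarray(lams),
        "offset": offsets,
        "cv": cvs,
        "dl_quantile": dl_q,
    }
    truth = SyntheticTruth(
        factor_of_analyte=pd.Series(factors, index=meta.index),
        lambda_of_analyte=pd.Series(lams, index=meta.index),
        duplicate_cv_of_analyte=pd.Series(cvs, index=meta.index),
        survival_betas=dict(design.survival_betas),
        trait_couplings=dict(design.trait_couplings),
        factor_loadings=lam_factor,
    )
    return panel, truth


def _standardize_binary(b: np.ndarray) -> np.ndarray:
    p = b.mean()
    s = math.sqrt(p * (1 - p)) if 0 < p < 1 else 1.0
    return (b - p) / s


def _simulate_clinical_and_factors(
    design: SimDesign, profile: CovariateProfile, rng: np.random.Generator
):
    n = profile.n_samples
    K = design.n_factors
    Z = rng.standard_normal((n, K))

    sex = (rng.random(n) < profile.female_p).astype(int)
    cvd = (rng.random(n) < profile.cvd_p).astype(int)
    smoking = (rng.random(n) < profile.smoking_p).astype(int)
    diabetes = (rng.random(n) < profile.diabetes_p).astype(int)
    antihyp = (rng.random(n) < profile.antihyp_p).astype(int)

    couplings = design.trait_couplings
    # binary couplings rotate the factor toward the (standardized) trait
    if "sex" in couplings:
        k, r = couplings["sex"]
        Z[:, k] = r * _standardize_binary(sex) + math.sqrt(1 - r**2) * Z[:, k]

    def coupled(mean, sd, trait):
        if trait in couplings:
            k, r = couplings[trait]
            base = r * Z[:, k] + math.sqrt(1 - r**2) * rng.standard_normal(n)
        else:
            base = rng.standard_normal(n)
        return mean + sd * base, base

    gfr, gfr_std = coupled(profile.gfr_mean, profile.gfr_sd, "gfr")
    gfr = np.clip(gfr, 5.0, None)
    glucose, _ = coupled(profile.glucose_mean, profile.glucose_sd, "glucose")
    glucose = np.clip(glucose, 40.0, None)
    log2_urine, _ = coupled(
        profile.log2_urine_mean, profile.log2_urine_sd, "log2_urine"
    )
    # CKD-style enrolment couples age to GFR (sicker kidneys enter younger)
    r_ag = profile.age_gfr_corr
    age = profile.age_mean + profile.age_sd * (
        r_ag * gfr_std + math.sqrt(1 - r_ag**2) * rng.standard_normal(n)
    )
    chol = profile.chol_mean + profile.chol_sd * rng.standard_normal(n)
    hdl = np.clip(profile.hdl_mean + profile.hdl_sd * rng.standard_normal(n), 10, None)
    sbp = profile.sbp_mean + profile.sbp_sd * rng.standard_normal(n)
    bmi = np.clip(profile.bmi_mean + profile.bmi_sd * rng.standard_normal(n), 14, None)

    clinical = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "gfr": gfr,
            "cvd": cvd,
            "smoking": smoking,
            "diabetes": diabetes,
            "glucose": glucose,
            profile.urine_col: np.exp2(log2_urine),
            "sbp": sbp,
            "antihypertensive": antihyp,
            "hdl": hdl,
            "cholesterol": chol,
            "bmi": bmi,
        }
    )
    if profile.centers is not None:
        clinical["center"] = rng.choice(
            list(profile.centers), size=n, p=list(profile.center_probs)
        )
    return clinical, Z


def _simulate_outcome(
    design: SimDesign,
    profile: CovariateProfile,
    clinical: pd.DataFrame,
    Z: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(clinical)
    ref = design.profile  # centring always at the discovery means
    eta = np.zeros(n)
    for k, beta in design.survival_betas.items():
        eta += beta * Z[:, int(k)]
    centres = {
        "age": ref.age_mean,
        "gfr": ref.gfr_mean,
        "sex": 0.0,
        "cvd": 0.0,
        "smoking": 0.0,
        "diabetes": 0.0,
    }
    for cov, beta in design.covariate_log_hazards.items():
        eta += beta * (clinical[cov].to_numpy(dtype=float) - centres.get(cov, 0.0))
    rate = design.baseline_rate * profile.hazard_multiplier
    u = rng.random(n)
    shape = design.weibull_shape
    t_event = (-np.log(u) / (rate * np.exp(eta))) ** (1.0 / shape)
    c = rng.uniform(profile.censor_low, profile.censor_high, n)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=clinical.index)


def _measure(
    u_log2: np.ndarray, panel: dict, rng: np.random.Generator
) -> np.ndarray:
    """Raw-scale measurement: multiplicative log-normal noise per analyte."""
    noise = rng.standard_normal(u_log2.shape) * (panel["cv"] / _LN2)
    return np.exp2(u_log2 + panel["offset"] + noise)


def simulate_cohort(
    design: SimDesign,
    seed: int,
    profile: CovariateProfile | None = None,
    _panel_truth=None,
) -> tuple[CohortBundle, SyntheticTruth]:
    """Generate one cohort; returns the bundle and the generative truth."""
    design.validate()
    profile = profile or design.profile
    rng = np.random.default_rng(seed)
    if _panel_truth is None:
        panel, truth = _build_panel(design, rng)
    else:
        panel, truth = _panel_truth
    n = profile.n_samples
    if design.n_duplicate_pairs > n:
        raise OmodError("more duplicate pairs than samples")

    clinical, Z = _simulate_clinical_and_factors(design, profile, rng)
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    clinical.index = pd.Index(sample_ids, name="sample_id")

    # specimen-level log2 signal: lambda * Z_factor + biological noise
    lam = panel["lam"]
    fac = np.where(panel["factor"] >= 0, panel["factor"], 0)
    u = lam * Z[:, fac] + rng.normal(0.0, design.noise_sd, (n, len(lam)))

    values = _measure(u, panel, rng)
    # blind duplicates: re-measure the first n_duplicate_pairs specimens
    dup_idx = np.arange(design.n_duplicate_pairs)
    dup_ids = [f"{sample_ids[i]}_dup" for i in dup_idx]
    dup_values = _measure(u[dup_idx], panel, rng)

    all_values = np.vstack([values, dup_values])
    all_ids = sample_ids + dup_ids
    df = pd.DataFrame(
        all_values, index=pd.Index(all_ids, name="sample_id"), columns=panel["meta"].index
    )
    # detection-limit left-censoring per metabolite
    for j in np.flatnonzero(panel["dl_quantile"] > 0):
        col = df.columns[j]
        dl = np.quantile(df[col].to_numpy()[:n], panel["dl_quantile"][j])
        df.loc[df[col] < dl, col] = np.nan

    abundances = AnalyteMatrix(df, panel["meta"].copy(), "raw")
    outcome = _simulate_outcome(design, profile, clinical, Z, rng)
    bundle = CohortBundle(
        abundances=abundances,
        clinical=clinical,
        outcome=outcome,
        duplicates=[(sample_ids[i], dup_ids[j]) for j, i in enumerate(dup_idx)],
    )
    bundle.factor_scores = pd.DataFrame(  # attached for truth-based tests
        Z, index=clinical.index, columns=[f"Z{k}" for k in range(design.n_factors)]
    )
    return bundle, truth


def simulate_pair(
    design: SimDesign, seed: int
) -> tuple[CohortBundle, CohortBundle, SyntheticTruth]:
    """Discovery + validation cohorts sharing one analyte panel and truth.

    The validation cohort redraws samples and covariates from the shifted
    profile but reuses the analyte->factor map and loadings, so module
    transfer has a well-defined ground truth.
    """
    rng = np.random.default_rng(seed)
    panel, truth = _build_panel(design, rng)
    s1, s2 = rng.integers(0, 2**31 - 1, size=2)
    disc, _ = simulate_cohort(design, int(s1), design.profile, (panel, truth))
    val, _ = simulate_cohort(
        design, int(s2), design.validation_profile, (panel, truth)
    )
    return disc, val, truth


def censoring_fraction(bundle: CohortBundle) -> float:
    """Fraction of samples censored (event == 0)."""
    if "event" not in bundle.outcome:
        raise OmodError("outcome table lacks an event column")
    return float((bundle.outcome["event"] == 0).mean())
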