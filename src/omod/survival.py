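"""Cox proportional-hazards association of module PCs with mortality.

Each exported module PC (in discovery-SD units) enters its own Cox model
alongside the cohort's covariate set; Bonferroni adjustment is over the
number of PCs tested.  Partial-likelihood maximization is delegated to
statsmodels' PHReg with Breslow tie handling by default.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .datatypes import CoxResult, OmodError, ScoreMatrix

log = logging.getLogger(__name__)

#: general-population discovery cohort covariate set
DISCOVERY_COVARIATES = (
    "age",
    "sex",
    "center",
    "gfr",
    "cvd",
    "smoking",
    "diabetes",
    "glucose",
    "acr",
    "sbp",
    "antihypertensive",
    "hdl",
    "cholesterol",
    "bmi",
)

#: CKD validation cohort covariate set (no diabetes / antihypertensive /
#: center variation by design; 24 h urine protein replaces ACR)
VALIDATION_COVARIATES = (
    "age",
    "sex",
    "gfr",
    "cvd",
    "smoking",
    "glucose",
    "upro24",
    "sbp",
    "hdl",
    "cholesterol",
    "bmi",
)

_URINE = ("acr", "upro24")


def linear_spline(x: pd.Series, knot: float) -> pd.DataFrame:
    """Linear-spline basis {x, max(x - knot, 0)} allowing a slope change."""
    return pd.DataFrame(
        {x.name: x.astype(float), f"{x.name}_gt{knot:g}": np.maximum(x - knot, 0.0)}
    )


def build_covariates(
    clinical: pd.DataFrame,
    profile: tuple[str, ...] = DISCOVERY_COVARIATES,
    chol_knot: float = 200.0,
    bmi_knot: float = 25.0,
) -> pd.DataFrame:
    """Numeric Cox design matrix for one cohort.

    Total cholesterol and BMI enter as linear splines (knots 200 mg/dL and
    25 kg/m2), urine protein is log2-transformed, and a categorical center
    is one-hot encoded against a reference level.
    """
    pieces = []
    for cov in profile:
        if cov not in clinical.columns:
            raise OmodError(f"covariate {cov!r} missing from the clinical table")
        col = clinical[cov]
        if cov == "cholesterol":
            pieces.append(linear_spline(col, chol_knot))
        elif cov == "bmi":
            pieces.append(linear_spline(col, bmi_knot))
        elif cov in _URINE:
            if (col <= 0).any():
                raise OmodError(f"non-positive {cov} values cannot be log2-transformed")
            pieces.append(np.log2(col.astype(float)).rename(f"log2_{cov}"))
        elif cov == "center":
            dummies = pd.get_dummies(col, prefix="center", drop_first=True)
            pieces.append(dummies.astype(float))
        else:
            pieces.append(col.astype(float))
    design = pd.concat(pieces, axis=1)
    if design.isna().any().any():
        bad = design.columns[design.isna().any()]
        raise OmodError(f"missing values in covariates: {list(bad)}")
    return design


def cox_fit(
    pc_scores: pd.Series,
    covariates: pd.DataFrame | None,
    outcome: pd.DataFrame,
    ties: str = "breslow",
    module_id: int = 0,
    pc: int = 1,
    covariate_set: str = "custom",
) -> CoxResult:
    """Cox PH fit of mortality on one standardized PC plus covariates.

    Returns the hazard ratio per discovery SD with Wald 95% CI and p-value.
    Non-convergence (score norm above 1e-6) is flagged on the result, not
    silently ignored.
    """
    idx = outcome.index
    X = pc_scores.loc[idx].to_frame("pc_score")
    if covariates is not None and len(covariates.columns):
        X = pd.concat([X, covariates.loc[idx]], axis=1)
    if X.isna().any().any():
        raise OmodError("missing values in the Cox design matrix")
    time = outcome["time"].to_numpy(dtype=float)
    event = outcome["event"].to_numpy(dtype=float)
    model = PHReg(time, X.to_numpy(dtype=float), status=event, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="newton", disp=False, maxiter=200)
    params = np.asarray(res.params, dtype=float)
    grad_norm = float(np.linalg.norm(model.score(params)))
    converged = bool(np.isfinite(grad_norm) and grad_norm < 1e-6)
    if not converged:
        log.warning(
            "Cox fit for m%d_pc%d did not converge (score norm %.3g)",
            module_id, pc, grad_norm,
        )
    beta = params[0]
    se = float(np.asarray(res.bse)[0])
    z = beta / se
    return CoxResult(
        module_id=module_id,
        pc=pc,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(2.0 * stats.norm.sf(abs(z))),
        n=len(time),
        events=int(event.sum()),
        covariate_set=covariate_set,
        converged=converged,
    )


def associate_mortality(
    scores: ScoreMatrix,
    covariates: pd.DataFrame,
    outcome: pd.DataFrame,
    ties: str = "breslow",
    covariate_set: str = "discovery",
) -> list[CoxResult]:
    """One Cox model per exported PC (scores must be in discovery-SD units)."""
    if not scores.standardized:
        raise OmodError("scores must be standardized to discovery-SD units")
    results = []
    common = scores.sample_ids.intersection(outcome.index)
    for col in scores.scores.columns:
        mid, pc = col[1:].split("_pc")
        results.append(
            cox_fit(
                scores.scores.loc[common, col],
                covariates.loc[common],
                outcome.loc[common],
                ties=ties,
                module_id=int(mid),
                pc=int(pc),
                covariate_set=covariate_set,
            )
        )
    return results


def bonferroni_select(
    results: list[CoxResult], alpha: float = 0.05, m: int | None = None
) -> list[CoxResult]:
    """Flag results with p strictly below alpha/m; m defaults to the number
    of tested PCs.  Returns the significant subset (inputs are annotated)."""
    if m is None:
        m = len(results)
    if m < 1:
        raise OmodError("m must be >= 1")
    threshold = alpha / m
    selected = []
    for r in results:
        r.m_tests = m
        r.significant = bool(r.p < threshold)
        if r.significant:
            selected.append(r)
    return selected
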