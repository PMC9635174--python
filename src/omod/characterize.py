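"""Cross-sectional characterization of module PCs against clinical traits."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnalyteMatrix, OmodError, ScoreMatrix, TraitAssociation
from .network import spearman_corr

log = logging.getLogger(__name__)

#: clinical columns used as traits when present (center is categorical and
#: urine protein is log2-transformed before modeling)
DEFAULT_TRAITS = (
    "age",
    "sex",
    "gfr",
    "acr",
    "upro24",
    "hdl",
    "cholesterol",
    "sbp",
    "bmi",
    "glucose",
    "cvd",
    "smoking",
)

URINE_TRAITS = ("acr", "upro24")


def _trait_vector(clinical: pd.DataFrame, trait: str) -> pd.Series:
    x = clinical[trait].astype(float)
    if trait in URINE_TRAITS:
        if (x <= 0).any():
            raise OmodError(f"non-positive {trait} values cannot be log2-transformed")
        x = np.log2(x)
    return x


def trait_regressions(
    scores: ScoreMatrix,
    clinical: pd.DataFrame,
    traits: list[str] | None = None,
) -> list[TraitAssociation]:
    """Univariable OLS of every module PC on every trait.

    For each (PC, trait) pair: slope with Wald 95% CI, R-squared (equal to
    the squared Pearson correlation in the univariable case) and the
    Spearman correlation.  Complete-case per trait; constant traits are
    skipped with a log entry.
    """
    if traits is None:
        traits = [t for t in DEFAULT_TRAITS if t in clinical.columns]
    out: list[TraitAssociation] = []
    common = scores.sample_ids.intersection(clinical.index)
    frame = scores.scores.loc[common]
    clin = clinical.loc[common]
    for trait in traits:
        x_full = _trait_vector(clin, trait)
        ok = x_full.notna()
        x = x_full[ok]
        if x.nunique() <= 1:
            log.info("trait %s is constant; skipped", trait)
            continue
        xv = x.to_numpy()
        for col in frame.columns:
            y = frame.loc[ok, col].to_numpy()
            res = stats.linregress(xv, y)
            tcrit = stats.t.ppf(0.975, len(xv) - 2)
            rho = stats.spearmanr(xv, y).statistic
            mid, pc = col[1:].split("_pc")
            out.append(
                TraitAssociation(
                    module_id=int(mid),
                    pc=int(pc),
                    trait=trait,
                    beta=float(res.slope),
                    ci_low=float(res.slope - tcrit * res.stderr),
                    ci_high=float(res.slope + tcrit * res.stderr),
                    r2=float(res.rvalue**2),
                    spearman=float(rho),
                    n=len(xv),
                )
            )
    return out


def residualize_age(clinical: pd.DataFrame) -> pd.Series:
    """Residuals of OLS of age on GFR (mean-zero, exactly GFR-orthogonal).

    Used when a cohort's enrolment couples age to kidney function (a CKD
    trial admits younger patients with worse kidneys), which distorts raw
    age-PC correlations relative to a general-population cohort.
    """
    age = clinical["age"].astype(float)
    gfr = clinical["gfr"].astype(float)
    if gfr.nunique() <= 1:
        raise OmodError("GFR is constant; cannot residualize age on it")
    slope, intercept = np.polyfit(gfr, age, 1)
    return age - (intercept + slope * gfr)


def module_layout(
    m: AnalyteMatrix, analytes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-D classical (metric) MDS of one module's within-module dissimilarity
    d = 1 - |Spearman rho|.

    Returns centered coordinates (reflection fixed so the first analyte has
    non-negative coordinates) and the pairwise |rho| edge weights.
    """
    if len(analytes) < 2:
        raise OmodError("module layout needs at least 2 components")
    rho = spearman_corr(m.values[list(analytes)].to_numpy())
    d = 1.0 - np.abs(rho)
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1][:2]
    coords = np.zeros((n, 2))
    for axis, idx in enumerate(order):
        lam = max(w[idx], 0.0)
        coords[:, axis] = v[:, idx] * math.sqrt(lam)
        if coords[0, axis] < 0:
            coords[:, axis] *= -1
    coord_df = pd.DataFrame(coords, index=analytes, columns=["x", "y"])
    rows = [
        (analytes[i], analytes[j], float(abs(rho[i, j])))
        for i in range(n)
        for j in range(i + 1, n)
    ]
    edges = pd.DataFrame(rows, columns=["analyte_i", "analyte_j", "weight"])
    return coord_df, edges
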