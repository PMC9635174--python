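"""Cross-cohort transfer of a frozen module model.

Discovery module memberships, PC loadings, means and SDs are applied
unchanged to a validation cohort.  Transferability is profiled as the mean
Spearman correlation of each module's components with its first PC, compared
between cohorts; replication testing re-runs the Cox association for the
discovery-significant PCs only, with a Bonferroni threshold over that count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AnalyteMatrix,
    CoxResult,
    ModuleModel,
    OmodError,
    ScoreMatrix,
)
from .scores import _colwise_spearman
from .survival import cox_fit


def apply_model(
    model: ModuleModel, m_val: AnalyteMatrix, standardize: bool = True
) -> ScoreMatrix:
    """Score a cohort with a frozen discovery model.

    Validation columns are z-scored with the DISCOVERY means/SDs stored in
    the model, projected onto the discovery loadings, and (by default)
    standardized to discovery-SD units via the stored PC score SDs.  A pure
    function of (model, matrix): no validation statistic enters.
    """
    cols: dict[str, np.ndarray] = {}
    have = set(m_val.values.columns)
    for mid in model.module_ids():
        pcs = model.modules[mid]
        missing = [a for a in pcs.analytes if a not in have]
        if missing:
            raise OmodError(
                f"module {mid} analytes absent from the matrix: {missing[:5]}"
            )
        X = m_val.values[pcs.analytes].to_numpy(dtype=float)
        Z = (X - pcs.means) / pcs.sds
        scores = Z @ pcs.loadings[:, : pcs.n_exported]
        if standardize:
            scores = scores / pcs.pc_sds[: pcs.n_exported]
        for c in range(scores.shape[1]):
            cols[f"m{mid}_pc{c + 1}"] = scores[:, c]
    return ScoreMatrix(
        pd.DataFrame(cols, index=m_val.values.index), standardized=standardize
    )


@dataclass
class TransferReport:
    """Per-module transferability profile plus the overall statistic."""

    per_module: pd.DataFrame  # module, mean_corr_discovery, mean_corr_validation,
    #                           delta, drop, excluded
    overall_spearman: float
    overall_pearson: float
    drop_threshold: float = -0.1

    @property
    def fraction_dropped(self) -> float:
        ok = ~self.per_module["excluded"]
        return float(self.per_module.loc[ok, "drop"].mean())

    @property
    def fraction_improved(self) -> float:
        ok = ~self.per_module["excluded"]
        return float((self.per_module.loc[ok, "delta"] > 0).mean())


def _mean_component_pc1_corr(
    model: ModuleModel, matrix: AnalyteMatrix, mid: int
) -> float:
    """Mean Spearman correlation of a module's component columns with its
    PC1 score in the given cohort (scored with the frozen model)."""
    pcs = model.modules[mid]
    X = matrix.values[pcs.analytes].to_numpy(dtype=float)
    pc1 = ((X - pcs.means) / pcs.sds) @ pcs.loadings[:, 0]
    if np.ptp(pc1) == 0:
        return np.nan
    return float(_colwise_spearman(X, pc1).mean())


def transferability(
    model: ModuleModel,
    m_disc: AnalyteMatrix,
    m_val: AnalyteMatrix,
    drop_threshold: float = -0.1,
) -> TransferReport:
    """Compare within-module coherence between cohorts under one model.

    Modules whose validation columns are all constant are flagged and
    excluded from the overall correlation-of-averages.
    """
    rows = []
    for mid in model.module_ids():
        pcs = model.modules[mid]
        const = bool(
            (m_val.values[pcs.analytes].nunique(axis=0) <= 1).all()
        )
        r_d = _mean_component_pc1_corr(model, m_disc, mid)
        r_v = np.nan if const else _mean_component_pc1_corr(model, m_val, mid)
        excluded = const or not np.isfinite(r_v)
        delta = r_v - r_d if not excluded else np.nan
        rows.append(
            {
                "module_id": mid,
                "n_components": pcs.n_components,
                "mean_corr_discovery": r_d,
                "mean_corr_validation": r_v,
                "delta": delta,
                "drop": bool(delta < drop_threshold) if not excluded else False,
                "excluded": excluded,
            }
        )
    per_module = pd.DataFrame(rows)
    ok = per_module[~per_module["excluded"]]
    if len(ok) >= 2:
        sp = stats.spearmanr(
            ok["mean_corr_discovery"], ok["mean_corr_validation"]
        ).statistic
        pe = stats.pearsonr(
            ok["mean_corr_discovery"], ok["mean_corr_validation"]
        ).statistic
    else:
        sp = pe = np.nan
    return TransferReport(
        per_module=per_module,
        overall_spearman=float(sp),
        overall_pearson=float(pe),
        drop_threshold=drop_threshold,
    )


def replicate_associations(
    discovery_significant: list[CoxResult],
    val_scores: ScoreMatrix,
    val_covariates: pd.DataFrame,
    val_outcome: pd.DataFrame,
    alpha: float = 0.05,
    ties: str = "breslow",
) -> list[CoxResult]:
    """Replication Cox tests in the validation cohort.

    Only discovery-significant PCs are tested; the Bonferroni denominator is
    their count.  Each returned result carries ``significant`` (replicated at
    alpha/m) and a ``direction_consistent`` attribute (sign of log HR equal
    across cohorts).
    """
    m = len(discovery_significant)
    if m == 0:
        return []
    out = []
    common = val_scores.sample_ids.intersection(val_outcome.index)
    for disc in discovery_significant:
        col = f"m{disc.module_id}_pc{disc.pc}"
        if col not in val_scores.scores.columns:
            raise OmodError(f"validation scores lack column {col}")
        res = cox_fit(
            val_scores.scores.loc[common, col],
            val_covariates.loc[common],
            val_outcome.loc[common],
            ties=ties,
            module_id=disc.module_id,
            pc=disc.pc,
            covariate_set="validation",
        )
        res.m_tests = m
        res.significant = bool(res.p < alpha / m)
        res.direction_consistent = bool(res.direction == disc.direction)
        out.append(res)
    return out
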