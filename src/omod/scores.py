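"""Module aggregation by principal components.

Each module's analyte submatrix is z-scored by discovery mean/SD and
decomposed by PCA.  Highly correlated modules (first-PC correlation above a
threshold) are merged and refitted.  Up to three PCs are exported per module,
or fewer once they account for half the module variance.  The fitted object
(:class:`~omod.datatypes.ModuleModel`) freezes means, SDs, loadings, sign
orientations and discovery score SDs, so it can be applied unchanged to a
second cohort.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import RunConfig
from .datatypes import (
    AnalyteMatrix,
    ModuleModel,
    ModulePartition,
    ModulePCs,
    OmodError,
    ScoreMatrix,
)


def _colwise_spearman(cols: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Spearman correlation of each column of ``cols`` with ``ref``."""
    rr = rankdata(ref)
    rr = (rr - rr.mean()) / rr.std()
    out = np.empty(cols.shape[1])
    for j in range(cols.shape[1]):
        cj = rankdata(cols[:, j])
        s = cj.std()
        out[j] = 0.0 if s == 0 else float(np.mean((cj - cj.mean()) / s * rr))
    return out


def _fit_one_module(
    X: np.ndarray,
    analytes: list[str],
    module_id: int,
    max_pcs: int,
    rank_pca: bool = False,
    merged_from: list[int] | None = None,
) -> tuple[ModulePCs, np.ndarray]:
    """PCA of one module's z-scored submatrix; returns the frozen model and
    the raw (unstandardized) discovery scores for the kept PCs."""
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        zero = [analytes[j] for j in np.flatnonzero(sd == 0)]
        raise OmodError(
            f"module {module_id} has zero-variance analytes {zero}; "
            "these should have been filtered in preprocessing"
        )
    Z = (X - mu) / sd
    W = np.apply_along_axis(rankdata, 0, Z) if rank_pca else Z
    if rank_pca:
        W = (W - W.mean(axis=0)) / W.std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(W, full_matrices=False)
    var_fractions = S**2 / np.sum(S**2)
    k = int(min(max_pcs, len(S)))
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * S[:k]

    # orientation: PC1 points along the module (mean component correlation
    # >= 0); higher PCs make their largest-|loading| entry positive
    if _colwise_spearman(Z, scores[:, 0]).mean() < 0:
        loadings[:, 0] *= -1
        scores[:, 0] *= -1
    for c in range(1, k):
        lead = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[lead, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1

    model = ModulePCs(
        module_id=module_id,
        analytes=list(analytes),
        means=mu,
        sds=sd,
        loadings=loadings,
        var_fractions=var_fractions,
        pc_sds=scores.std(axis=0, ddof=1),
        n_exported=k,
        merged_from=list(merged_from or []),
    )
    return model, scores


def fit_module_pcs(
    m: AnalyteMatrix,
    part: ModulePartition,
    max_pcs: int = 3,
    rank_pca: bool = False,
) -> tuple[ModuleModel, ScoreMatrix]:
    """Fit per-module PCAs on the finalized discovery matrix.

    Background analytes are not aggregated.  Raw scores are returned
    (discovery SD standardization is a separate, explicit step).
    """
    if m.scale_state != "log2":
        raise OmodError("fit_module_pcs expects the finalized log2 matrix")
    models: dict[int, ModulePCs] = {}
    cols: dict[str, np.ndarray] = {}
    for mid, analytes in part.modules().items():
        X = m.values[analytes].to_numpy(dtype=float)
        model, scores = _fit_one_module(X, analytes, mid, max_pcs, rank_pca)
        models[mid] = model
        for c in range(scores.shape[1]):
            cols[f"m{mid}_pc{c + 1}"] = scores[:, c]
    frame = pd.DataFrame(cols, index=m.values.index)
    return ModuleModel(modules=models), ScoreMatrix(frame, standardized=False)


def _pc1_correlations(model: ModuleModel, scores: ScoreMatrix) -> pd.DataFrame:
    ids = model.module_ids()
    mat = np.column_stack([scores.scores[f"m{i}_pc1"].to_numpy() for i in ids])
    return pd.DataFrame(np.corrcoef(mat, rowvar=False), index=ids, columns=ids)


def merge_correlated(
    model: ModuleModel,
    scores: ScoreMatrix,
    part: ModulePartition,
    m: AnalyteMatrix,
    threshold: float = 0.9,
    abs_merge: bool = False,
    max_pcs: int = 3,
    rank_pca: bool = False,
) -> tuple[ModulePartition, ModuleModel, ScoreMatrix]:
    """Iteratively merge module pairs whose first PCs correlate above
    ``threshold`` (signed by default), refitting after every merge.

    The merged module keeps the smaller id; provenance is recorded both on
    the partition and on the module model.  Terminates at the fixed point
    where no pair exceeds the threshold.
    """
    models = dict(model.modules)
    frame = scores.scores.copy()
    assignment = part.assignment.copy()
    history = list(part.merge_history)

    while len(models) > 1:
        ids = sorted(models)
        mat = np.column_stack([frame[f"m{i}_pc1"].to_numpy() for i in ids])
        corr = np.corrcoef(mat, rowvar=False)
        cval = np.abs(corr) if abs_merge else corr
        np.fill_diagonal(cval, -np.inf)
        best, pair = -np.inf, None
        for a, b in itertools.combinations(range(len(ids)), 2):
            if cval[a, b] > best + 1e-15:
                best, pair = cval[a, b], (ids[a], ids[b])
        if best <= threshold or pair is None:
            break
        lo, hi = min(pair), max(pair)
        merged_analytes = models[lo].analytes + models[hi].analytes
        merged_analytes = [a for a in assignment.index if a in set(merged_analytes)]
        provenance = sorted(
            set([lo, hi] + models[lo].merged_from + models[hi].merged_from)
        )
        X = m.values[merged_analytes].to_numpy(dtype=float)
        new_model, new_scores = _fit_one_module(
            X, merged_analytes, lo, max_pcs, rank_pca, merged_from=provenance
        )
        frame = frame.drop(
            columns=[c for c in frame.columns if c.startswith((f"m{lo}_", f"m{hi}_"))]
        )
        for c in range(new_scores.shape[1]):
            frame[f"m{lo}_pc{c + 1}"] = new_scores[:, c]
        models[lo] = new_model
        del models[hi]
        assignment[assignment == hi] = lo
        history.append({"merged": [lo, hi], "into": lo, "pc1_correlation": float(best)})

    ordered = [
        f"m{i}_pc{c + 1}"
        for i in sorted(models)
        for c in range(models[i].n_exported)
    ]
    return (
        ModulePartition(assignment=assignment, merge_history=history),
        ModuleModel(modules=models),
        ScoreMatrix(frame[ordered], standardized=False),
    )


def select_exported_pcs(
    model: ModuleModel, max_pcs: int = 3, var_target: float = 0.50
) -> ModuleModel:
    """Per module, export the smallest K whose cumulative variance fraction
    reaches ``var_target``, capped at ``max_pcs`` (export the cap if even
    that falls short)."""
    out: dict[int, ModulePCs] = {}
    for mid, pcs in model.modules.items():
        avail = pcs.loadings.shape[1]
        cum = np.cumsum(pcs.var_fractions[:avail])
        reach = np.flatnonzero(cum >= var_target - 1e-12)
        k = int(reach[0]) + 1 if len(reach) else avail
        k = min(k, max_pcs, avail)
        out[mid] = ModulePCs(
            module_id=pcs.module_id,
            analytes=pcs.analytes,
            means=pcs.means,
            sds=pcs.sds,
            loadings=pcs.loadings,
            var_fractions=pcs.var_fractions,
            pc_sds=pcs.pc_sds,
            n_exported=k,
            merged_from=pcs.merged_from,
        )
    return ModuleModel(modules=out, seed=model.seed)


def standardize_scores(scores: ScoreMatrix, model: ModuleModel) -> ScoreMatrix:
    """Divide each score column by its DISCOVERY-cohort SD from the model
    (never the current cohort's SD), yielding per-discovery-SD units."""
    if scores.standardized:
        return scores
    frame = scores.scores.copy()
    for col in frame.columns:
        mid, pc = col[1:].split("_pc")
        pcs = model.modules.get(int(mid))
        if pcs is None or int(pc) > len(pcs.pc_sds):
            raise OmodError(f"model lacks a discovery SD for column {col}")
        frame[col] = frame[col] / pcs.pc_sds[int(pc) - 1]
    return ScoreMatrix(frame, standardized=True)


def exported_scores(scores: ScoreMatrix, model: ModuleModel) -> ScoreMatrix:
    """Restrict a score matrix to the model's exported PC columns."""
    return ScoreMatrix(scores.scores[model.score_columns()], scores.standardized)


def fit_scores(
    m: AnalyteMatrix, part: ModulePartition, cfg: RunConfig
) -> tuple[ModulePartition, ModuleModel, ScoreMatrix]:
    """Full module-aggregation stage: fit, merge, select, standardize."""
    model, scores = fit_module_pcs(m, part, cfg.max_pcs, cfg.rank_pca)
    part, model, scores = merge_correlated(
        model, scores, part, m, cfg.merge_threshold, cfg.abs_merge,
        cfg.max_pcs, cfg.rank_pca,
    )
    model = select_exported_pcs(model, cfg.max_pcs, cfg.pc_var_target)
    scores = exported_scores(scores, model)
    return part, model, standardize_scores(scores, model)
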