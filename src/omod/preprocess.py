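"""Harmonized preprocessing of protein and metabolite abundance matrices.

Proteins: blind-duplicate Bland-Altman CV filter (raw scale), log2 transform,
5-SD winsorization.  Metabolites: xenobiotic exclusion, missingness filter,
median-1 scaling, log2 transform, low-variance filter.  Both arms are then
restricted to the analytes present in both cohorts, missing cells are imputed
with the analyte's observed minimum and all values capped at 5 SD.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .datatypes import AnalyteMatrix, CohortBundle, OmodError

log = logging.getLogger(__name__)


def log2_proteins(m: AnalyteMatrix) -> AnalyteMatrix:
    """log2-transform a raw-scale matrix (used for the protein arm).

    Raw aptamer readouts are right-skewed; the log2 transform symmetrizes
    them.  Missing cells stay missing.
    """
    if m.scale_state != "raw":
        raise OmodError("log2_proteins expects a raw-scale matrix")
    bad = m.values.columns[(m.values <= 0).any()]
    if len(bad):
        raise OmodError(f"non-positive observed values in analytes: {list(bad)[:5]}")
    return AnalyteMatrix(np.log2(m.values), m.meta.copy(), "log2")


def winsorize(m: AnalyteMatrix, k: float = 5.0) -> AnalyteMatrix:
    """Clamp observed values to mean +/- k SD per analyte (log2 scale).

    Mean and SD are computed once from the original column, so the pass is
    single-shot and deterministic; a constant column is left unchanged.
    """
    if m.scale_state != "log2":
        raise OmodError("winsorize expects a log2-scale matrix")
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1).fillna(0.0)
    clipped = m.values.clip(lower=mu - k * sd, upper=mu + k * sd, axis=1)
    return AnalyteMatrix(clipped, m.meta.copy(), "log2")


def bland_altman_cv(a: np.ndarray, b: np.ndarray) -> float:
    """Duplicate-based coefficient of variation on the raw scale.

    Within-pair SD estimate sqrt(mean((a-b)^2) / 2), divided by the grand
    mean of all duplicate measurements.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        return np.nan
    a, b = a[ok], b[ok]
    sd = np.sqrt(np.mean((a - b) ** 2) / 2.0)
    grand = np.mean(np.concatenate([a, b]))
    return float(sd / grand)


def cv_filter(
    m: AnalyteMatrix,
    duplicates: list[tuple[str, str]],
    cv_max: float = 0.5,
) -> tuple[AnalyteMatrix, pd.DataFrame]:
    """Drop analytes whose blind-duplicate Bland-Altman CV exceeds ``cv_max``.

    Returns the filtered matrix and an exclusion table (analyte, cv).
    Requires a raw-scale matrix and at least one duplicate pair.
    """
    if m.scale_state != "raw":
        raise OmodError("cv_filter operates on raw-scale values")
    if not duplicates:
        raise OmodError("cv_filter needs at least one blind duplicate pair")
    first = [a for a, _ in duplicates]
    second = [b for _, b in duplicates]
    va = m.values.loc[first].to_numpy()
    vb = m.values.loc[second].to_numpy()
    cvs = np.array(
        [bland_altman_cv(va[:, j], vb[:, j]) for j in range(va.shape[1])]
    )
    drop = m.values.columns[cvs > cv_max]
    excluded = pd.DataFrame(
        {
            "analyte_id": drop,
            "rule": "duplicate_cv",
            "statistic": cvs[cvs > cv_max],
        }
    )
    keep = [c for c in m.values.columns if c not in set(drop)]
    log.info("cv_filter: %d analytes in, %d excluded", m.values.shape[1], len(drop))
    return m.subset_analytes(keep), excluded


def metabolite_prep(
    m: AnalyteMatrix,
    missing_max: float = 0.80,
    var_min: float = 0.01,
) -> tuple[AnalyteMatrix, pd.DataFrame]:
    """Metabolite arm: xenobiotic / missingness / scaling / variance steps.

    Drops xenobiotic-flagged metabolites, then metabolites missing in more
    than ``missing_max`` of samples; scales the rest to a median of 1 (so the
    log2 median is 0), log2-transforms, and drops metabolites with log2
    variance below ``var_min``.  Returns the processed matrix and an
    exclusion table with one row per dropped analyte (analyte, rule,
    triggering statistic).
    """
    if m.scale_state != "raw":
        raise OmodError("metabolite_prep expects raw-scale metabolites")
    rows = []
    vals = m.values.copy()

    xeno = m.meta.index[m.meta["xenobiotic"]]
    for a in xeno:
        rows.append((a, "xenobiotic", 1.0))
    vals = vals.drop(columns=list(xeno))

    miss_frac = vals.isna().mean(axis=0)
    too_missing = miss_frac.index[miss_frac > missing_max]
    for a in too_missing:
        rows.append((a, "missingness", float(miss_frac[a])))
    vals = vals.drop(columns=list(too_missing))

    medians = vals.median(axis=0)
    if (medians <= 0).any():
        bad = medians.index[medians <= 0]
        raise OmodError(f"non-positive medians for metabolites: {list(bad)[:5]}")
    vals = np.log2(vals / medians)

    variances = vals.var(axis=0, ddof=1).fillna(0.0)
    low_var = variances.index[variances < var_min]
    for a in low_var:
        rows.append((a, "low_variance", float(variances[a])))
    vals = vals.drop(columns=list(low_var))

    excluded = pd.DataFrame(rows, columns=["analyte_id", "rule", "statistic"])
    log.info(
        "metabolite_prep: %d in, %d excluded (%d xenobiotic, %d missing, %d low-var)",
        m.values.shape[1], len(rows), len(xeno), len(too_missing), len(low_var),
    )
    out = AnalyteMatrix(vals, m.meta.loc[vals.columns].copy(), "log2")
    return out, excluded


def finalize(m: AnalyteMatrix, k: float = 5.0) -> AnalyteMatrix:
    """Impute missing cells with the analyte's observed minimum, then cap all
    values at mean +/- k SD (moments recomputed after imputation)."""
    if m.scale_state != "log2":
        raise OmodError("finalize expects a log2-scale matrix")
    vals = m.values.copy()
    mins = vals.min(axis=0)
    empty = mins.index[mins.isna()]
    if len(empty):
        raise OmodError(
            f"analytes with no observed values reached finalize: {list(empty)[:5]}"
        )
    vals = vals.fillna(mins)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    vals = vals.clip(lower=mu - k * sd, upper=mu + k * sd, axis=1)
    return AnalyteMatrix(vals, m.meta.copy(), "log2")


def harmonize(
    a: AnalyteMatrix, b: AnalyteMatrix
) -> tuple[AnalyteMatrix, AnalyteMatrix]:
    """Restrict both matrices to the shared analyte panel, in a common order."""
    shared = [c for c in a.values.columns if c in set(b.values.columns)]
    if not shared:
        raise OmodError("no shared analytes between cohorts")
    return a.subset_analytes(shared), b.subset_analytes(shared)


def preprocess_cohort(
    bundle: CohortBundle, cfg: RunConfig
) -> tuple[AnalyteMatrix, pd.DataFrame]:
    """Per-cohort preprocessing (before harmonization and imputation).

    Protein arm: CV filter on raw values using the blind duplicates, log2,
    winsorize.  Metabolite arm: ``metabolite_prep``.  Duplicate rows are
    dropped after the CV filter; the returned matrix covers the primary
    samples only and is on the log2 scale, still holding missing cells.
    """
    raw = bundle.abundances
    proteins = raw.subset_analytes(raw.analytes_of_type("protein"))
    metabolites = raw.subset_analytes(raw.analytes_of_type("metabolite"))

    proteins, excl_cv = cv_filter(proteins, bundle.duplicates, cfg.cv_max)
    primary = list(bundle.primary_samples)
    proteins = proteins.subset_samples(primary)
    metabolites = metabolites.subset_samples(primary)

    proteins = winsorize(log2_proteins(proteins), cfg.winsor_k)
    metabolites, excl_met = metabolite_prep(
        metabolites, cfg.missing_max, cfg.var_min
    )

    vals = pd.concat([proteins.values, metabolites.values], axis=1)
    meta = pd.concat([proteins.meta, metabolites.meta], axis=0)
    exclusions = pd.concat([excl_cv, excl_met], ignore_index=True)
    return AnalyteMatrix(vals, meta, "log2"), exclusions


def preprocess_pair(
    discovery: CohortBundle, validation: CohortBundle, cfg: RunConfig
) -> tuple[AnalyteMatrix, AnalyteMatrix, pd.DataFrame]:
    """Full two-cohort preprocessing: per-cohort filters, intersection of the
    surviving panels, then minimum imputation + capping per cohort."""
    m_d, excl_d = preprocess_cohort(discovery, cfg)
    m_v, excl_v = preprocess_cohort(validation, cfg)
    m_d, m_v = harmonize(m_d, m_v)
    m_d = finalize(m_d, cfg.winsor_k)
    m_v = finalize(m_v, cfg.winsor_k)
    excl_d["cohort"] = "discovery"
    excl_v["cohort"] = "validation"
    return m_d, m_v, pd.concat([excl_d, excl_v], ignore_index=True)
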