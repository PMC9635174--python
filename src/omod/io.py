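"""Tab-delimited readers/writers for every pipeline artifact.

Dialect: UTF-8, tab-delimited, header row, first column sample id (abundance
/ clinical / outcome tables) or analyte id (metadata).  Missing cells are
empty or "NA".  Writers prepend a ``# seed=N`` comment line when a seed is
known; readers skip ``#`` comment lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .datatypes import (
    AnalyteMatrix,
    CohortBundle,
    CoxResult,
    ModuleModel,
    ModulePartition,
    OmodError,
    TraitAssociation,
)

log = logging.getLogger(__name__)

_NA = ["", "NA"]


def _read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        index_col=index_col,
        comment="#",
        na_values=_NA,
        keep_default_na=False,
    )


def _write_tsv(df: pd.DataFrame, path, seed: int | None = None, index=True) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", na_rep="NA", index=index)


def read_cohort(directory) -> CohortBundle:
    """Read one cohort from ``abundances.tsv``, ``meta.tsv``, ``clinical.tsv``,
    ``outcome.tsv`` and ``duplicates.tsv`` in ``directory``.

    Hard errors: duplicated sample ids; non-positive outcome times (the
    offending sample ids are named).  Metadata rows for unknown analytes are
    ignored with a warning.
    """
    directory = Path(directory)
    values = _read_tsv(directory / "abundances.tsv")
    values.columns.name = "analyte_id"
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique()
        raise OmodError(f"duplicate sample ids in abundances: {list(dups)[:5]}")
    meta = _read_tsv(directory / "meta.tsv")
    unknown = meta.index.difference(values.columns)
    if len(unknown):
        log.warning(
            "meta.tsv describes %d analytes absent from abundances; ignored",
            len(unknown),
        )
        meta = meta.drop(index=unknown)
    missing_meta = values.columns.difference(meta.index)
    if len(missing_meta):
        raise OmodError(f"analytes without metadata: {list(missing_meta)[:5]}")
    meta = meta.loc[values.columns]
    meta["xenobiotic"] = meta["xenobiotic"].astype(bool)

    clinical = _read_tsv(directory / "clinical.tsv")
    outcome = _read_tsv(directory / "outcome.tsv")
    bad = outcome.index[outcome["time"] <= 0]
    if len(bad):
        raise OmodError(f"non-positive outcome times for samples: {list(bad)}")

    dup_path = directory / "duplicates.tsv"
    duplicates: list[tuple[str, str]] = []
    if dup_path.exists():
        dup = _read_tsv(dup_path, index_col=None)
        duplicates = [tuple(r) for r in dup[["sample_id", "duplicate_id"]].itertuples(index=False)]

    # align sample order: primary samples first, in clinical order
    order = [s for s in clinical.index if s in set(values.index)]
    extra = [s for s in values.index if s not in set(clinical.index)]
    values = values.loc[order + extra]
    return CohortBundle(
        abundances=AnalyteMatrix(values, meta, "raw"),
        clinical=clinical,
        outcome=outcome.loc[[s for s in clinical.index if s in set(outcome.index)]],
        duplicates=duplicates,
    )


def write_cohort(bundle: CohortBundle, directory, seed: int | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_tsv(bundle.abundances.values, directory / "abundances.tsv", seed)
    _write_tsv(bundle.abundances.meta, directory / "meta.tsv", seed)
    _write_tsv(bundle.clinical, directory / "clinical.tsv", seed)
    _write_tsv(bundle.outcome, directory / "outcome.tsv", seed)
    dup = pd.DataFrame(bundle.duplicates, columns=["sample_id", "duplicate_id"])
    _write_tsv(dup, directory / "duplicates.tsv", seed, index=False)


def associations_frame(results: list[CoxResult]) -> pd.DataFrame:
    """Association table, sorted by p ascending (deterministic columns)."""
    rows = [
        {
            "module_id": r.module_id,
            "pc": r.pc,
            "hr": r.hr,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p,
            "n": r.n,
            "events": r.events,
            "significant": int(bool(r.significant)),
            "m_tests": r.m_tests if r.m_tests is not None else len(results),
            "covariate_set": r.covariate_set,
            "converged": int(r.converged),
            "direction_consistent": int(getattr(r, "direction_consistent", True)),
        }
        for r in results
    ]
    cols = [
        "module_id", "pc", "hr", "ci_low", "ci_high", "p", "n", "events",
        "significant", "m_tests", "covariate_set", "converged",
        "direction_consistent",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["p", "module_id", "pc"], kind="mergesort").reset_index(
        drop=True
    )


def write_associations(results: list[CoxResult], path, seed: int | None = None) -> None:
    _write_tsv(associations_frame(results), path, seed, index=False)


def characterization_frame(assocs: list[TraitAssociation]) -> pd.DataFrame:
    cols = ["module_id", "pc", "trait", "beta", "ci_low", "ci_high", "r2",
            "spearman", "n"]
    rows = [{c: getattr(a, c) for c in cols} for a in assocs]
    return pd.DataFrame(rows, columns=cols)


def write_characterization(
    assocs: list[TraitAssociation], path, seed: int | None = None
) -> None:
    _write_tsv(characterization_frame(assocs), path, seed, index=False)


def write_partition(part: ModulePartition, path, seed: int | None = None) -> None:
    df = part.assignment.rename("module_id").to_frame()
    merged_into = {}
    for ev in part.merge_history:
        for m in ev["merged"]:
            if m != ev["into"]:
                merged_into[m] = ev["into"]
    df["merge_history"] = [
        ";".join(
            f"{a}->{b}" for a, b in merged_into.items() if b == mid
        )
        for mid in df["module_id"]
    ]
    _write_tsv(df, path, seed)


def read_partition(path) -> ModulePartition:
    df = _read_tsv(path)
    return ModulePartition(assignment=df["module_id"].astype(int))


def write_model(model: ModuleModel, path) -> None:
    Path(path).write_text(model.to_json())


def read_model(path) -> ModuleModel:
    return ModuleModel.from_json(Path(path).read_text())


def write_scores(scores, path, seed: int | None = None) -> None:
    _write_tsv(scores.scores, path, seed)


def read_scores(path, standardized: bool = True):
    from .datatypes import ScoreMatrix

    return ScoreMatrix(_read_tsv(path), standardized=standardized)


def write_transfer_report(report, path, seed: int | None = None) -> None:
    df = report.per_module.copy()
    df["overall_spearman"] = report.overall_spearman
    df["overall_pearson"] = report.overall_pearson
    _write_tsv(df, path, seed, index=False)


def write_truth(truth, path) -> None:
    import json

    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))
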