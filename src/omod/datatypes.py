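"""Core containers shared by every pipeline stage.

The central object is :class:`AnalyteMatrix`, a samples x analytes abundance
table (proteins from an aptamer panel, metabolites from untargeted MS) with a
missingness mask and per-analyte metadata.  Modules of correlated analytes are
represented by :class:`ModulePartition`; the frozen, transferable per-module
PCA is a :class:`ModuleModel`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

ANALYTE_TYPES = ("protein", "metabolite")

BACKGROUND = 0  # module id reserved for unassigned analytes


class OmodError(ValueError):
    """Raised on contract violations anywhere in the pipeline."""


@dataclass
class AnalyteMatrix:
    """Samples x analytes abundance matrix.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, columns are analyte ids.  Missing
        measurements are NaN; the missing mask is derived from them.
    meta
        DataFrame indexed by analyte id with columns ``analyte_type``
        (protein/metabolite), ``xenobiotic`` (bool) and ``display_name``.
    scale_state
        ``"raw"`` (positive abundances) or ``"log2"``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale_state: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_state not in ("raw", "log2"):
            raise OmodError(f"unknown scale_state {self.scale_state!r}")
        if list(self.values.columns) != list(self.meta.index):
            # allow meta supersets only through explicit alignment
            missing = set(self.values.columns) - set(self.meta.index)
            if missing:
                raise OmodError(f"analytes without metadata: {sorted(missing)[:5]}")
            self.meta = self.meta.loc[self.values.columns]
        if self.meta.index.has_duplicates:
            raise OmodError("duplicate analyte ids in metadata")
        bad = self.meta.loc[
            self.meta["xenobiotic"] & (self.meta["analyte_type"] != "metabolite")
        ]
        if len(bad):
            raise OmodError(
                f"xenobiotic flag on non-metabolites: {list(bad.index)[:5]}"
            )

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def analyte_ids(self) -> pd.Index:
        return self.values.columns

    def analytes_of_type(self, analyte_type: str) -> list[str]:
        if analyte_type not in ANALYTE_TYPES:
            raise OmodError(f"unknown analyte type {analyte_type!r}")
        return list(self.meta.index[self.meta["analyte_type"] == analyte_type])

    def subset_analytes(self, analyte_ids) -> "AnalyteMatrix":
        analyte_ids = list(analyte_ids)
        return AnalyteMatrix(
            self.values[analyte_ids].copy(),
            self.meta.loc[analyte_ids].copy(),
            self.scale_state,
        )

    def subset_samples(self, sample_ids) -> "AnalyteMatrix":
        return AnalyteMatrix(
            self.values.loc[list(sample_ids)].copy(), self.meta.copy(), self.scale_state
        )

    def copy(self) -> "AnalyteMatrix":
        return AnalyteMatrix(self.values.copy(), self.meta.copy(), self.scale_state)


@dataclass
class CohortBundle:
    """One cohort: abundances plus clinical covariates and survival outcome.

    ``duplicates`` lists blind duplicate pairs (sample_id, duplicate_id) that
    measured the same specimen; duplicate rows exist in ``abundances`` only.
    """

    abundances: AnalyteMatrix
    clinical: pd.DataFrame
    outcome: pd.DataFrame  # columns: time, event
    duplicates: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        samples = set(self.abundances.sample_ids)
        for tab, name in ((self.clinical, "clinical"), (self.outcome, "outcome")):
            extra = set(tab.index) - samples
            if extra:
                raise OmodError(f"{name} table has unknown samples: {sorted(extra)[:5]}")
        for a, b in self.duplicates:
            if a not in samples or b not in samples:
                raise OmodError(f"duplicate pair ({a}, {b}) references unknown sample")
        bad = self.outcome.index[self.outcome["time"] <= 0]
        if len(bad):
            raise OmodError(f"non-positive follow-up time for samples: {list(bad)}")

    @property
    def primary_samples(self) -> pd.Index:
        """Samples that carry clinical/outcome data (excludes blind duplicates)."""
        return self.clinical.index


@dataclass
class ModulePartition:
    """Analyte -> module assignment; module 0 is the background (unassigned)."""

    assignment: pd.Series  # index analyte id, int module id
    merge_history: list[dict] = field(default_factory=list)

    def module_ids(self) -> list[int]:
        ids = sorted(set(self.assignment) - {BACKGROUND})
        return ids

    def members(self, module_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == module_id])

    def modules(self) -> dict[int, list[str]]:
        return {m: self.members(m) for m in self.module_ids()}

    def background(self) -> list[str]:
        return list(self.assignment.index[self.assignment == BACKGROUND])

    def n_modules(self) -> int:
        return len(self.module_ids())


def mean_assigned_per_module(
    n_analytes: int, n_unassigned: int, n_modules: int
) -> float:
    """Mean number of assigned analytes per (non-background) module."""
    if n_modules < 1:
        raise OmodError("need at least one module")
    return (n_analytes - n_unassigned) / n_modules


@dataclass
class ModulePCs:
    """Frozen PCA of one module, fitted in the discovery cohort.

    Scores in a new cohort are ``((X - means) / sds) @ loadings / pc_sds`` —
    every statistic here comes from discovery, which is what makes hazard
    ratios "per discovery SD" and scores comparable across cohorts.
    """

    module_id: int
    analytes: list[str]
    means: np.ndarray  # (p,) discovery column means, log2 scale
    sds: np.ndarray  # (p,) discovery column SDs
    loadings: np.ndarray  # (p, k) orthonormal columns, sign-oriented
    var_fractions: np.ndarray  # full spectrum, sums to 1
    pc_sds: np.ndarray  # (k,) discovery score SDs
    n_exported: int = 0
    merged_from: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.analytes)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("means", "sds", "loadings", "var_fractions", "pc_sds"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModulePCs":
        d = dict(d)
        for key in ("means", "sds", "loadings", "var_fractions", "pc_sds"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class ModuleModel:
    """The transferable artifact: per-module frozen PCAs plus provenance."""

    modules: dict[int, ModulePCs]
    seed: int | None = None

    def module_ids(self) -> list[int]:
        return sorted(self.modules)

    def score_columns(self) -> list[str]:
        cols = []
        for m in self.module_ids():
            mod = self.modules[m]
            cols += [f"m{m}_pc{k + 1}" for k in range(mod.n_exported)]
        return cols

    def to_json(self, indent: int | None = 1) -> str:
        payload = {
            "format": "omod-module-model",
            "version": 1,
            "seed": self.seed,
            "modules": {str(m): pcs.to_dict() for m, pcs in self.modules.items()},
        }
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "ModuleModel":
        payload = json.loads(text)
        if payload.get("format") != "omod-module-model":
            raise OmodError("not a module-model document")
        modules = {
            int(m): ModulePCs.from_dict(d) for m, d in payload["modules"].items()
        }
        return cls(modules=modules, seed=payload.get("seed"))


@dataclass
class ScoreMatrix:
    """Samples x module-PC score matrix.

    ``standardized`` marks discovery-SD units (each column divided by the
    discovery-cohort score SD stored in the model).
    """

    scores: pd.DataFrame
    standardized: bool = False

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    def column(self, module_id: int, pc: int) -> pd.Series:
        return self.scores[f"m{module_id}_pc{pc}"]


@dataclass
class CoxResult:
    """One Cox proportional-hazards association of a module PC with mortality."""

    module_id: int
    pc: int
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    covariate_set: str
    converged: bool = True
    significant: bool | None = None
    m_tests: int | None = None

    @property
    def log_hr(self) -> float:
        return float(np.log(self.hr))

    @property
    def direction(self) -> int:
        return int(np.sign(self.log_hr))


@dataclass
class TraitAssociation:
    """Univariable OLS of a module PC score on one clinical trait."""

    module_id: int
    pc: int
    trait: str
    beta: float
    ci_low: float
    ci_high: float
    r2: float
    spearman: float
    n: int
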