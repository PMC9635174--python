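"""Run configuration: every tunable of the pipeline with its default."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

from .datatypes import OmodError


@dataclass
class RunConfig:
    """All pipeline tunables.

    Preprocessing: values beyond ``winsor_k`` SDs on the log2 scale are
    winsorized; proteins with blind-duplicate Bland-Altman CV above ``cv_max``
    are dropped; metabolites with missing fraction above ``missing_max`` or
    log2 variance below ``var_min`` are dropped.

    Network/modules: each analyte proposes its ``edges_per_node`` strongest
    Spearman partners; average-linkage trees on 1-|rho| are cut at
    ``cut_height``; clusters smaller than ``min_module_size`` fall into the
    background module; modules whose first PCs correlate above
    ``merge_threshold`` are merged; up to ``max_pcs`` PCs are exported per
    module, or fewer once they explain ``pc_var_target`` of module variance.

    Survival: Bonferroni at ``alpha`` over the exported-PC count; total
    cholesterol and BMI enter the Cox model as linear splines with knots at
    ``chol_knot`` mg/dL and ``bmi_knot`` kg/m2.
    """

    winsor_k: float = 5.0
    cv_max: float = 0.5
    missing_max: float = 0.80
    var_min: float = 0.01
    edges_per_node: int = 20
    cut_height: float = 0.75
    min_module_size: int = 2
    merge_threshold: float = 0.9
    abs_merge: bool = False
    max_pcs: int = 3
    pc_var_target: float = 0.50
    rank_pca: bool = False
    signed_network: bool = False
    alpha: float = 0.05
    chol_knot: float = 200.0
    bmi_knot: float = 25.0
    ties: str = "breslow"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cv_max > 0:
            raise OmodError("cv_max must be positive")
        if not 0 < self.missing_max < 1:
            raise OmodError("missing_max must be in (0, 1)")
        if self.min_module_size < 2:
            raise OmodError("min_module_size must be >= 2")
        if not 0 < self.pc_var_target <= 1:
            raise OmodError("pc_var_target must be in (0, 1]")
        if not 0 < self.cut_height <= 1:
            raise OmodError("cut_height must be in (0, 1]")
        if self.edges_per_node < 1:
            raise OmodError("edges_per_node must be >= 1")
        if not 1 <= self.max_pcs:
            raise OmodError("max_pcs must be >= 1")
        if self.ties not in ("breslow", "efron"):
            raise OmodError("ties must be 'breslow' or 'efron'")
        if not 0 < self.alpha < 1:
            raise OmodError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise OmodError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
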