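import numpy as np
import pandas as pd
import pytest

from omod import (
    AnalyteMatrix,
    RunConfig,
    SimDesign,
    cluster_modules,
    fit_scores,
    preprocess_pair,
    simulate_pair,
    spearman_network,
)


def make_matrix(values: np.ndarray, analyte_types=None, prefix="A", scale="log2"):
    """Small AnalyteMatrix around a plain array (helper for unit tests)."""
    n, p = values.shape
    ids = [f"{prefix}{j + 1}" for j in range(p)]
    if analyte_types is None:
        analyte_types = ["protein"] * p
    meta = pd.DataFrame(
        {
            "analyte_type": analyte_types,
            "xenobiotic": [False] * p,
            "display_name": ids,
        },
        index=pd.Index(ids, name="analyte_id"),
    )
    df = pd.DataFrame(values, columns=ids,
                      index=pd.Index([f"s{i + 1}" for i in range(n)], name="sample_id"))
    return AnalyteMatrix(df, meta, scale)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig(seed=7)


@pytest.fixture(scope="session")
def cohort_pair():
    """Default-design discovery/validation pair with ground truth."""
    disc, val, truth = simulate_pair(SimDesign(), seed=7)
    return disc, val, truth


@pytest.fixture(scope="session")
def pipeline(cohort_pair, default_config):
    """Full discovery-side pipeline run shared across test modules."""
    disc, val, truth = cohort_pair
    cfg = default_config
    m_d, m_v, exclusions = preprocess_pair(disc, val, cfg)
    net = spearman_network(m_d, cfg.edges_per_node)
    part = cluster_modules(net, m_d, cfg.cut_height, cfg.min_module_size)
    part, model, scores = fit_scores(m_d, part, cfg)
    return {
        "discovery": disc,
        "validation": val,
        "truth": truth,
        "m_d": m_d,
        "m_v": m_v,
        "exclusions": exclusions,
        "network": net,
        "partition": part,
        "model": model,
        "scores": scores,
        "cfg": cfg,
    }
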