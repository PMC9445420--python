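"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import retarget as rt
from retarget.netgraph import impute_unweighted_edges


@pytest.fixture(scope="session")
def small_cfg() -> rt.SimulationConfig:
    """Desk-scale-but-cheap study conditions for unit tests."""
    return rt.SimulationConfig(
        n_genes=300, n_tumor=20, n_normal=20, n_features=30,
        n_informative_features=8, n_duplicate_features=4,
        n_high_missing_features=3, n_drugs=30, n_planted_drugs=3,
        targets_per_drug=5, seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return rt.simulate_all(small_cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_cfg, small_sim):
    """DE labels, split and filtered features on the small simulation."""
    expr, feats, graph, drugs, ic50, truth = small_sim
    de = rt.differential_expression(expr)
    labels = rt.assign_labels(de)
    split = rt.stratified_split(labels, seed=small_cfg.seed)
    filtered, counts, report = rt.filter_pipeline(
        feats, labels, seed=small_cfg.seed,
        train_genes=split.index[split == "train"])
    return {"de": de, "labels": labels, "split": split, "features": filtered,
            "filter_counts": counts, "graph": impute_unweighted_edges(graph),
            "truth": truth}


@pytest.fixture(scope="session")
def default_pipeline():
    """The default synthetic scenario run once through DE + features + GAT.

    Shared by the acceptance checks; expensive (about a minute).
    """
    seed = 1
    cfg = rt.SimulationConfig(seed=seed)
    expr, feats, graph, drugs, ic50, truth = rt.simulate_all(cfg)
    de = rt.differential_expression(expr)
    labels = rt.assign_labels(de)
    split = rt.stratified_split(labels, seed=seed)
    filtered, counts, _ = rt.filter_pipeline(
        feats, labels, seed=seed, train_genes=split.index[split == "train"])
    graph = impute_unweighted_edges(graph)
    model = rt.GeneClassifier(filtered, labels, graph, split,
                              rt.GATConfig(seed=seed))
    res = model.fit(n_random=4, grid_refine=True, seed=seed)
    return {"cfg": cfg, "expr": expr, "features": filtered, "graph": graph,
            "drugs": drugs, "ic50": ic50, "truth": truth, "de": de,
            "labels": labels, "split": split, "filter_counts": counts,
            "model": model, "results": res, "seed": seed}
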