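"""Gene classifier: graph-attention model over the interaction graph.

statsmodels-style surface: :class:`GeneClassifier` is built from the
filtered feature table, the label partition, the interaction graph and
the train/validation/test split; :meth:`GeneClassifier.fit` runs the
random-then-grid hyperparameter search with 3-fold cross-validation on
the training genes (mean validation AUROC as the selection metric),
retrains on the full train split with early stopping on the validation
split, and returns a :class:`ClassifierResults` carrying the test-set
evaluation, the Youden operating threshold, per-gene scores and the
node embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, asdict

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (f1_score, precision_score, recall_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold

from . import gat
from .de import POSITIVE_LABELS
from .netgraph import impute_unweighted_edges
from .featsel import Normalizer

__all__ = ["GeneClassifier", "ClassifierResults", "EvalReport",
           "youden_threshold", "evaluate_scores", "baseline_tree_ensemble",
           "default_search_space"]

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Threshold metrics plus AUROC for one evaluation partition."""

    auroc: float
    precision: float
    recall: float
    f1: float
    threshold: float = 0.5
    n: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_scores(y_true, y_score, threshold: float = 0.5) -> EvalReport:
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    y_pred = (y_score >= threshold).astype(int)
    auroc = roc_auc_score(y_true, y_score) if len(np.unique(y_true)) == 2 else float("nan")
    return EvalReport(
        auroc=float(auroc),
        precision=float(precision_score(y_true, y_pred, zero_division=0)),
        recall=float(recall_score(y_true, y_pred, zero_division=0)),
        f1=float(f1_score(y_true, y_pred, zero_division=0)),
        threshold=float(threshold), n=len(y_true),
    )


def youden_threshold(y_true, y_score) -> float:
    """Threshold maximizing TPR - FPR; decision rule is score >= threshold.

    Candidates are the observed scores. Ties between maximizers are
    broken toward the larger threshold (the operating point with the
    lower false-positive rate), matching the conventional descending
    threshold scan of a ROC curve. With a single score value the Youden
    index is 0 at that degenerate threshold.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = max(int(y_true.sum()), 1)
    n_neg = max(int(len(y_true) - y_true.sum()), 1)
    best_t, best_j = None, -np.inf
    for t in np.sort(np.unique(y_score))[::-1]:
        pred = y_score >= t
        tpr = (pred & (y_true == 1)).sum() / n_pos
        fpr = (pred & (y_true == 0)).sum() / n_neg
        j = tpr - fpr
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def default_search_space() -> dict:
    return {
        "hidden_dim": [8, 16, 32],
        "heads": [2, 4, 8],
        "dropout": [0.0, 0.3, 0.5],
        "learning_rate": ("log_uniform", 1e-4, 1e-2),
    }


def _sample_config(space: dict, base: gat.GATConfig,
                   rng: np.random.Generator) -> gat.GATConfig:
    kw = {}
    for key, spec in space.items():
        if isinstance(spec, tuple) and spec[0] == "log_uniform":
            kw[key] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        else:
            kw[key] = spec[int(rng.integers(len(spec)))]
    return replace(base, **kw)


def _grid_neighbours(best: gat.GATConfig, space: dict) -> list[gat.GATConfig]:
    """3-point grid per hyperparameter around the random-search winner."""
    out = []
    for key, spec in space.items():
        if isinstance(spec, tuple) and spec[0] == "log_uniform":
            v = getattr(best, key)
            for f in (0.5, 2.0):
                cand = float(np.clip(v * f, spec[1], spec[2]))
                out.append(replace(best, **{key: cand}))
        else:
            vals = sorted(spec)
            i = vals.index(getattr(best, key))
            for j in (i - 1, i + 1):
                if 0 <= j < len(vals):
                    out.append(replace(best, **{key: vals[j]}))
    return out


class GeneClassifier:
    """Binary gene classifier on the annotation features + interaction graph.

    Parameters
    ----------
    features : DataFrame
        Filtered (un-normalized) feature table, genes x features; NaN =
        missing. Normalization statistics are fitted internally on the
        train partition only.
    labels : Series
        Gene -> label from the DE partition; positive_up/positive_down
        are the positive class, negative the negative class; ambiguous
        genes are scored at prediction time.
    graph : networkx.Graph
        Weighted interaction graph. Genes absent from the graph attend
        only to themselves.
    split : Series
        Gene -> {train, validation, test}.
    """

    def __init__(self, features: pd.DataFrame, labels: pd.Series,
                 graph: nx.Graph, split: pd.Series,
                 config: gat.GATConfig | None = None):
        self.features = features
        self.labels = labels.reindex(features.index)
        self.split = split
        self.config = config or gat.GATConfig()
        graph = impute_unweighted_edges(graph)
        self.genes = list(features.index)
        gene_pos = {g: i for i, g in enumerate(self.genes)}
        edges, weights = [], []
        for u, v, d in graph.edges(data=True):
            if u in gene_pos and v in gene_pos:
                edges.append((gene_pos[u], gene_pos[v]))
                weights.append(d.get("weight", 1.0))
        self._edges, self._weights = edges, weights
        self.normalizer = Normalizer.fit(
            features, split.index[split == "train"])
        self.X = self.normalizer.transform(features).values
        y = self.labels.isin(POSITIVE_LABELS).astype(int)
        self._y = y.values
        self._part_idx = {
            part: np.array([gene_pos[g] for g in split.index[split == part]
                            if g in gene_pos], dtype=np.intp)
            for part in ("train", "validation", "test")
        }

    def _edge_index(self, config: gat.GATConfig) -> gat.EdgeIndex:
        return gat.build_edge_index(len(self.genes), self._edges,
                                    self._weights, config.edge_weight_mode)

    def _cv_score(self, config: gat.GATConfig, seed: int, n_folds: int = 3,
                  max_reseed: int = 5, cv_max_epochs: int = 150,
                  cv_patience: int = 20) -> float:
        """Mean validation AUROC over stratified folds of the train genes.

        Candidate configurations are scored under a truncated epoch
        budget; only the final refit uses the full budget.
        """
        config = replace(config,
                         max_epochs=min(config.max_epochs, cv_max_epochs),
                         patience=min(config.patience, cv_patience))
        tr = self._part_idx["train"]
        y = self._y[tr]
        for attempt in range(max_reseed):
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=seed + attempt)
            folds = list(skf.split(tr, y))
            if all(len(np.unique(y[va])) == 2 and len(np.unique(y[fi])) == 2
                   for fi, va in folds):
                break
            log.warning("degenerate single-class fold; refolding with a new seed")
        ei = self._edge_index(config)
        scores = []
        for fit_i, val_i in folds:
            res = gat.train_gat(self.X, ei, replace(config, seed=seed),
                                tr[fit_i], y[fit_i], tr[val_i], y[val_i])
            proba = gat.predict_proba(res.params, self.X, ei, config)
            scores.append(roc_auc_score(y[val_i], proba[tr[val_i]]))
        return float(np.mean(scores))

    def fit(self, search_space: dict | None = None, n_random: int = 20,
            grid_refine: bool = True, seed: int = 0) -> "ClassifierResults":
        """Random search -> local grid refinement -> final retrain.

        ``n_random = 0`` skips the search and trains the constructor's
        config directly.
        """
        rng = np.random.default_rng(seed)
        cv_rows = []
        best_cfg, best_score = self.config, -np.inf
        if n_random > 0:
            space = search_space or default_search_space()
            cands = [_sample_config(space, self.config, rng)
                     for _ in range(n_random)]
            for cfg in cands:
                s = self._cv_score(cfg, seed)
                cv_rows.append({"stage": "random", **_cfg_row(cfg), "cv_auroc": s})
                if s > best_score:
                    best_score, best_cfg = s, cfg
            if grid_refine:
                for cfg in _grid_neighbours(best_cfg, space):
                    s = self._cv_score(cfg, seed)
                    cv_rows.append({"stage": "grid", **_cfg_row(cfg), "cv_auroc": s})
                    if s > best_score:
                        best_score, best_cfg = s, cfg
        ei = self._edge_index(best_cfg)
        tr, va, te = (self._part_idx[p] for p in ("train", "validation", "test"))
        res = gat.train_gat(self.X, ei, replace(best_cfg, seed=seed),
                            tr, self._y[tr], va, self._y[va])
        proba = gat.predict_proba(res.params, self.X, ei, best_cfg)
        thr = youden_threshold(self._y[va], proba[va]) if len(va) else 0.5
        report = evaluate_scores(self._y[te], proba[te], threshold=thr)
        return ClassifierResults(
            model=self, config=best_cfg, params=res.params,
            edge_index=ei, eval_report=report,
            cv_report=pd.DataFrame(cv_rows), youden=thr,
            scores=pd.Series(proba, index=self.genes, name="score"),
            train_history=res.history,
        )


def _cfg_row(cfg: gat.GATConfig) -> dict:
    return {"hidden_dim": cfg.hidden_dim, "heads": cfg.heads,
            "dropout": cfg.dropout, "learning_rate": cfg.learning_rate}


@dataclass
class ClassifierResults:
    """Fitted gene classifier: scores, operating thresholds, diagnostics."""

    model: GeneClassifier
    config: gat.GATConfig
    params: dict
    edge_index: gat.EdgeIndex
    eval_report: EvalReport
    cv_report: pd.DataFrame
    youden: float
    scores: pd.Series
    train_history: list

    def save(self, prefix) -> None:
        """Checkpoint: parameters to <prefix>.npz, config to <prefix>.json."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        np.savez(prefix.with_suffix(".npz"),
                 **{k: v.data for k, v in self.params.items()})
        prefix.with_suffix(".json").write_text(json.dumps(
            {"config": asdict(self.config), "youden": self.youden,
             "genes": self.model.genes}))

    @staticmethod
    def load_params(prefix):
        """Load a checkpoint; returns (params dict, config, youden, genes)."""
        import json
        from pathlib import Path

        from . import autodiff as ad
        from .gat import GATConfig

        prefix = Path(prefix)
        npz = np.load(prefix.with_suffix(".npz"))
        params = {k: ad.Tensor(npz[k], requires_grad=True) for k in npz.files}
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return params, GATConfig(**meta["config"]), meta["youden"], meta["genes"]

    def predict_ambiguous(self, cut: float = 0.9) -> pd.DataFrame:
        """Score table for the ambiguous genes.

        ``predicted_positive`` uses a strict ``score > cut`` rule (a gene
        scoring exactly at the cut is not called); ``above_youden``
        applies the validation-set Youden threshold.
        """
        amb = self.model.labels.index[self.model.labels == "ambiguous"]
        s = self.scores.loc[amb]
        return pd.DataFrame({
            "score": s,
            "above_youden": s >= self.youden,
            "predicted_positive": s > cut,
        })

    def predicted_genes(self, cut: float = 0.9) -> set:
        tab = self.predict_ambiguous(cut)
        return set(tab.index[tab["predicted_positive"]])

    def embeddings(self) -> pd.DataFrame:
        """Penultimate-layer node embeddings (deterministic forward pass)."""
        emb = gat.node_embeddings(self.params, self.model.X, self.edge_index,
                                  self.config)
        return pd.DataFrame(emb, index=self.model.genes)

    def plot_roc(self, ax=None):
        """ROC curve on the test partition."""
        from sklearn.metrics import roc_curve
        import matplotlib.pyplot as plt

        te = self.model._part_idx["test"]
        fpr, tpr, _ = roc_curve(self.model._y[te], self.scores.values[te])
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"GAT (AUROC = {self.eval_report.auroc:.2f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def summary(self) -> str:
        r = self.eval_report
        lines = [
            "Gene classifier (graph attention network)",
            "=" * 45,
            f"genes: {len(self.model.genes)}  "
            f"train/val/test: "
            + "/".join(str(len(self.model._part_idx[p]))
                       for p in ("train", "validation", "test")),
            f"config: hidden_dim={self.config.hidden_dim} "
            f"heads={self.config.heads} dropout={self.config.dropout} "
            f"lr={self.config.learning_rate:.2e}",
            f"Youden threshold (validation): {self.youden:.3f}",
            f"test AUROC:     {r.auroc:.3f}",
            f"test precision: {r.precision:.3f}",
            f"test recall:    {r.recall:.3f}",
            f"test F1:        {r.f1:.3f}",
        ]
        return "\n".join(lines)


def baseline_tree_ensemble(features: pd.DataFrame, labels: pd.Series,
                           split: pd.Series, seed: int = 0,
                           n_estimators: int = 300) -> EvalReport:
    """Seeded random-forest comparator on the same features, no graph."""
    norm = Normalizer.fit(features, split.index[split == "train"])
    X = norm.transform(features)
    y = labels.reindex(features.index).isin(POSITIVE_LABELS).astype(int)
    tr = split.index[split == "train"]
    te = split.index[split == "test"]
    rf = RandomForestClassifier(n_estimators=n_estimators,
                                random_state=int(seed), n_jobs=1)
    rf.fit(X.loc[tr].values, y.loc[tr].values)
    proba = rf.predict_proba(X.loc[te].values)[:, 1]
    return evaluate_scores(y.loc[te].values, proba)
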