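"""Annotation-feature filtering, stratified splitting and leakage-free
normalization.

The filter pipeline is order-fixed: missingness (> 40% missing dropped)
-> pairwise correlation (|r| > 0.98 on jointly observed entries, later
column dropped) -> cumulative importance (seeded random-forest
importances, minimal prefix reaching 0.99). Correlations are computed on
pairwise-complete observations *before* zero imputation, because imputed
zeros would manufacture correlation; zeros are imputed only at model
input, inside the normalizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .de import POSITIVE_LABELS
from .simulate import FeatureTable

__all__ = ["filter_missingness", "filter_correlation",
           "filter_cumulative_importance", "filter_pipeline",
           "stratified_split", "Normalizer"]

log = logging.getLogger(__name__)


def _as_df(ft) -> pd.DataFrame:
    return ft.matrix if isinstance(ft, FeatureTable) else ft


def filter_missingness(ft, threshold: float = 0.40) -> pd.DataFrame:
    """Drop features whose missing fraction strictly exceeds ``threshold``."""
    df = _as_df(ft)
    frac = df.isna().mean(axis=0)
    keep = frac.index[frac.values <= threshold]
    return df[keep]


def filter_correlation(ft, threshold: float = 0.98) -> pd.DataFrame:
    """Greedy scan in column order; drop the later column of any pair with
    |Pearson r| > threshold on jointly observed entries."""
    df = _as_df(ft)
    corr = df.corr(method="pearson")  # pairwise-complete by construction
    cols = list(df.columns)
    kept: list[str] = []
    for c in cols:
        r = corr.loc[c, kept] if kept else pd.Series(dtype=float)
        r = r.abs()
        if (r > threshold).any():
            continue
        # constant columns yield NaN correlations: treated as uncorrelated
        if kept and r.isna().all() and df[c].nunique(dropna=True) <= 1:
            log.info("feature %s is constant; correlation undefined, kept", c)
        kept.append(c)
    return df[kept]


def cumulative_prefix_count(importances, threshold: float = 0.99) -> int:
    """Size of the minimal descending-sorted prefix whose normalized
    cumulative importance reaches ``threshold``."""
    imp = np.asarray(importances, dtype=float)
    imp = imp / imp.sum()
    cum = np.cumsum(np.sort(imp)[::-1])
    return int(min(np.searchsorted(cum, threshold - 1e-12) + 1, len(imp)))


def filter_cumulative_importance(ft, labels: pd.Series, threshold: float = 0.99,
                                 seed: int = 0, train_genes=None,
                                 n_estimators: int = 300):
    """Keep the minimal importance-ranked prefix reaching cumulative 0.99.

    A seeded random-forest is fitted on the labeled (positive vs
    negative) genes — restricted to ``train_genes`` when given, to keep
    the scorer blind to validation/test genes. Missing entries are
    zero-imputed for the fit only. Returns (filtered table, report);
    the report lists every feature with its normalized importance and
    cumulative sum, mirroring a normalized-importance ranking.
    """
    df = _as_df(ft)
    y = labels.reindex(df.index)
    binary = y.isin(POSITIVE_LABELS + ("negative",))
    if train_genes is not None:
        binary &= y.index.isin(set(train_genes))
    genes = y.index[binary]
    if len(genes) < 2:
        raise ValueError("need at least two labeled genes to score importance")
    X = df.loc[genes].fillna(0.0).values
    yb = y.loc[genes].isin(POSITIVE_LABELS).astype(int).values
    rf = RandomForestClassifier(n_estimators=n_estimators,
                                random_state=int(seed), n_jobs=1)
    rf.fit(X, yb)
    imp = rf.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    order = np.argsort(-imp, kind="stable")
    cum = np.cumsum(imp[order])
    n_keep = cumulative_prefix_count(imp, threshold)
    keep_idx = np.sort(order[:n_keep])  # survivors in original column order
    report = pd.DataFrame({
        "feature": df.columns[order],
        "normalized_importance": imp[order],
        "cumulative_importance": cum,
        "kept": [i < n_keep for i in range(len(order))],
    })
    return df.iloc[:, keep_idx], report


def filter_pipeline(ft, labels: pd.Series, seed: int = 0, train_genes=None,
                    missing_threshold: float = 0.40,
                    corr_threshold: float = 0.98,
                    importance_threshold: float = 0.99):
    """Missingness -> correlation -> importance; returns (table, stage counts, report)."""
    df = _as_df(ft)
    counts = {"input": df.shape[1]}
    df = filter_missingness(df, missing_threshold)
    counts["after_missingness"] = df.shape[1]
    df = filter_correlation(df, corr_threshold)
    counts["after_correlation"] = df.shape[1]
    df, report = filter_cumulative_importance(df, labels, importance_threshold,
                                              seed=seed, train_genes=train_genes)
    counts["after_importance"] = df.shape[1]
    return df, counts, report


def _largest_remainder(n: int, fractions) -> list[int]:
    """Apportion n into integer parts matching fractions; ties favour
    earlier partitions (train > validation > test)."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def stratified_split(labels: pd.Series, fractions=(0.8, 0.1, 0.1),
                     seed: int = 0) -> pd.Series:
    """Per-class shuffled 80/10/10 split of positive and negative genes.

    Stratification is on the two training classes (positive = up or
    down, negative); ambiguous and excluded genes receive no partition.
    Rounding is largest-remainder. Deterministic under ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts = ("train", "validation", "test")
    out = {}
    for cls_genes in (labels.index[labels.isin(POSITIVE_LABELS)],
                      labels.index[labels == "negative"]):
        genes = np.array(sorted(cls_genes))
        rng.shuffle(genes)
        sizes = _largest_remainder(len(genes), fractions)
        pos = 0
        for part, k in zip(parts, sizes):
            for g in genes[pos:pos + k]:
                out[g] = part
            pos += k
    return pd.Series(out, name="partition", dtype=object)


@dataclass
class Normalizer:
    """Per-feature standardization fitted on the train partition only.

    Transform order: zero-impute missing entries, subtract the train
    mean, divide by the train SD (zero-variance columns pass through
    with scale 1). Applying to validation/test/ambiguous genes reuses
    the train statistics, so nothing leaks across partitions.
    """

    mean: pd.Series
    scale: pd.Series

    @classmethod
    def fit(cls, ft, train_genes) -> "Normalizer":
        df = _as_df(ft)
        train = df.loc[df.index.isin(set(train_genes))].fillna(0.0)
        if train.empty:
            raise ValueError("no train genes present in the feature table")
        mean = train.mean(axis=0)
        scale = train.std(axis=0, ddof=0)
        degenerate = scale <= 0
        if degenerate.any():
            log.info("%d zero-variance train columns passed through with "
                     "scale 1", int(degenerate.sum()))
        scale = scale.where(~degenerate, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, ft) -> pd.DataFrame:
        df = _as_df(ft)
        return (df[self.mean.index].fillna(0.0) - self.mean) / self.scale
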