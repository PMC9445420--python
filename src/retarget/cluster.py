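"""K-means clustering of trained node embeddings with silhouette-selected K."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .de import POSITIVE_LABELS

__all__ = ["select_k_and_cluster", "cluster_composition"]


def select_k_and_cluster(embeddings: pd.DataFrame, k_range=range(2, 16),
                         seed: int = 0, n_restarts: int = 10) -> pd.DataFrame:
    """Seeded K-means for each K; return the assignment maximizing the mean
    silhouette (Euclidean), ties toward the smaller K.

    Returns a DataFrame indexed by gene with a ``cluster`` column
    (ids 1..K) and attrs ``{"k": K, "silhouette": s}``.
    """
    X = embeddings.values
    n = X.shape[0]
    if np.allclose(X, X[0]):
        raise ValueError("all embeddings identical: silhouette is undefined, "
                         "cannot select a cluster count")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if len(ks) < len(list(k_range)):
        warnings.warn("k_range truncated to 2..n-1", stacklevel=2)
    if not ks:
        raise ValueError("k_range contains no feasible cluster counts")
    best = None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed))
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            continue
        s = silhouette_score(X, lab, metric="euclidean")
        if best is None or s > best[0] + 1e-12:
            best = (s, k, lab)
    s, k, lab = best
    out = pd.DataFrame({"cluster": lab + 1}, index=embeddings.index)
    out.attrs["k"] = int(k)
    out.attrs["silhouette"] = float(s)
    return out


def cluster_composition(assignment: pd.DataFrame, labels: pd.Series,
                        predicted_genes=frozenset()) -> pd.DataFrame:
    """Per-cluster fractions of the three display classes.

    Classes: ``de_positive`` (differential-expression positives),
    ``predicted`` (classifier-called ambiguous genes), ``other``.
    Fractions sum to 1 within each cluster.
    """
    predicted_genes = set(predicted_genes)
    lab = labels.reindex(assignment.index)
    cls = pd.Series("other", index=assignment.index, dtype=object)
    cls[lab.isin(POSITIVE_LABELS)] = "de_positive"
    cls[assignment.index.isin(predicted_genes)] = "predicted"
    tab = pd.crosstab(assignment["cluster"], cls)
    for col in ("de_positive", "predicted", "other"):
        if col not in tab:
            tab[col] = 0
    tab = tab[["de_positive", "predicted", "other"]]
    frac = tab.div(tab.sum(axis=1), axis=0)
    frac.columns = [f"frac_{c}" for c in frac.columns]
    out = pd.concat([tab.rename(columns=lambda c: f"n_{c}"), frac], axis=1)
    out["n_total"] = tab.sum(axis=1)
    out["frac_disease"] = frac["frac_de_positive"] + frac["frac_predicted"]
    return out
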