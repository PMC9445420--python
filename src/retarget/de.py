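"""Differential expression and the four-way gene label partition.

Fold change is the ratio of raw group means (tumor over normal);
significance comes from a moderated two-sample t-test on
log2(FPKM + pseudocount) with empirical-Bayes variance shrinkage
(limma-style squeezing of per-gene variances toward a fitted
scaled-inverse-chi-square prior), or a plain Welch t-test as a fallback.
Benjamini-Hochberg FDR over all tested genes.

Labeling rules (all thresholds strict as stated):

* FDR >= 0.05              -> excluded_fdr
* log2FC > 2               -> positive_up
* log2FC < -2              -> positive_down
* -0.3 < log2FC < 0.3      -> negative
* otherwise                -> ambiguous
* would-be positives on the pseudogene list -> excluded_pseudogene
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionMatrix

__all__ = ["differential_expression", "assign_labels", "squeeze_variances",
           "LABELS", "POSITIVE_LABELS"]

LABELS = ("positive_up", "positive_down", "negative", "ambiguous",
          "excluded_fdr", "excluded_pseudogene")
POSITIVE_LABELS = ("positive_up", "positive_down")


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton; y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    sample variances by moment matching on log variances, then returns
    the posterior variances (d0*s0^2 + df*s2) / (d0 + df) together with
    (d0, s0^2). d0 = inf collapses every variance to s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, 0.0, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0)
                            - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    if np.isinf(d0):
        post = np.full_like(s2, s0_2)
    else:
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, float(d0), s0_2


def differential_expression(expr: ExpressionMatrix, method: str = "moderated",
                            pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene two-group test; returns one row per gene.

    Columns: mean_tumor, mean_normal, fold_change, log2fc, p_value, fdr,
    zero_both (flag for genes expressed in neither group). The fold
    change uses raw group means; the test runs on
    log2(values + pseudocount).
    """
    tumor = expr.samples("tumor")
    normal = expr.samples("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("each group needs at least 2 samples")
    if (expr.values.values < 0).any():
        raise ValueError("expression values must be non-negative")
    X_t = expr.values[tumor].values
    X_n = expr.values[normal].values
    mean_t = X_t.mean(axis=1)
    mean_n = X_n.mean(axis=1)
    zero_both = (mean_t == 0) & (mean_n == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_t / mean_n
        log2fc = np.log2(fold)
    log2fc[zero_both] = 0.0
    fold[zero_both] = 1.0

    L_t = np.log2(X_t + pseudocount)
    L_n = np.log2(X_n + pseudocount)
    n1, n2 = L_t.shape[1], L_n.shape[1]
    diff = L_t.mean(axis=1) - L_n.mean(axis=1)
    if method == "moderated":
        df_resid = n1 + n2 - 2
        ss = ((L_t - L_t.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
            + ((L_n - L_n.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2 = ss / df_resid
        s2_post, d0, _ = squeeze_variances(s2, df_resid)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        # d0 = inf means the moderated t converges to a z-test
        df_total = 1e6 if np.isinf(d0) else df_resid + d0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        p[~np.isfinite(t)] = np.where(diff[~np.isfinite(t)] == 0, 1.0, 0.0)
    elif method == "welch":
        t, p = stats.ttest_ind(L_t, L_n, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.clip(p, 0.0, 1.0)
    p[zero_both] = 1.0
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "mean_tumor": mean_t, "mean_normal": mean_n, "fold_change": fold,
        "log2fc": log2fc, "p_value": p, "fdr": fdr, "zero_both": zero_both,
    }, index=expr.values.index.rename("gene"))


def assign_labels(de: pd.DataFrame, pseudogenes=frozenset()) -> pd.Series:
    """Partition every tested gene into exactly one of six labels."""
    pseudogenes = set(pseudogenes)
    missing = pseudogenes - set(de.index)
    if missing:
        warnings.warn(f"{len(missing)} pseudogenes absent from the DE table; "
                      "ignored", stacklevel=2)
    log2fc = de["log2fc"].values
    fdr = de["fdr"].values
    zero_both = de["zero_both"].values if "zero_both" in de else np.zeros(len(de), bool)
    labels = np.full(len(de), "ambiguous", dtype=object)
    labels[log2fc > 2] = "positive_up"
    labels[log2fc < -2] = "positive_down"
    labels[(log2fc > -0.3) & (log2fc < 0.3)] = "negative"
    is_pseudo = de.index.isin(pseudogenes)
    would_be_positive = np.isin(labels, POSITIVE_LABELS)
    labels[is_pseudo & would_be_positive] = "excluded_pseudogene"
    labels[(fdr >= 0.05) | zero_both] = "excluded_fdr"
    return pd.Series(labels, index=de.index, name="label")
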