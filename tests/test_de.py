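"""Differential expression: moderated test, BH-FDR, label partition rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import retarget as rt
from retarget.simulate import ExpressionMatrix
from retarget.de import squeeze_variances


def _make_expr(values, n_tumor, n_normal, genes=None):
    n = len(values)
    cols = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    df = pd.DataFrame(values, columns=cols,
                      index=genes or [f"g{i}" for i in range(n)])
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal,
                       index=cols, name="group")
    return ExpressionMatrix(values=df, groups=groups)


def bh_stepup(p):
    """Hand-executed Benjamini-Hochberg step-up (test oracle)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


@pytest.fixture(scope="module")
def limma_fixture():
    """Seeded two-group matrix whose moderated statistics were cross-checked
    against an independent reference implementation."""
    rng = np.random.default_rng(1234)
    n_genes, n1, n2 = 60, 5, 5
    base = np.exp(rng.normal(3, 1, n_genes))
    fc = np.where(np.arange(n_genes) < 15,
                  2.0 ** rng.uniform(1, 3, n_genes), 1.0)
    vals_t = base[:, None] * fc[:, None] * np.exp(
        0.4 * rng.standard_normal((n_genes, n1)))
    vals_n = base[:, None] * np.exp(0.4 * rng.standard_normal((n_genes, n2)))
    return _make_expr(np.hstack([vals_t, vals_n]), n1, n2,
                      genes=[f"g{i:03d}" for i in range(n_genes)])


def test_moderated_test_matches_reference_values(limma_fixture):
    """Frozen p-values and prior from a reference moderated-t fit."""
    de = rt.differential_expression(limma_fixture)
    expected = {
        "g000": 1.32289928566159e-08,
        "g001": 5.86053994590888e-10,
        "g002": 0.108118769561932,
        "g009": 0.0482061172658728,
        "g010": 0.000337056347876707,
        "g011": 0.00385523280384851,
        "g058": 0.632117112188409,
        "g059": 0.788958811134568,
    }
    for gene, p in expected.items():
        assert de.loc[gene, "p_value"] == pytest.approx(p, rel=1e-9)
    L = np.log2(limma_fixture.values.values + 1)
    s2 = ((L[:, :5] - L[:, :5].mean(1, keepdims=True)) ** 2).sum(1)
    s2 = (s2 + ((L[:, 5:] - L[:, 5:].mean(1, keepdims=True)) ** 2).sum(1)) / 8
    _, d0, s02 = squeeze_variances(s2, 8)
    assert d0 == pytest.approx(39.95354, abs=1e-4)
    assert s02 == pytest.approx(0.2757233, abs=1e-6)


def test_welch_fallback_agrees_with_scipy(limma_fixture):
    de = rt.differential_expression(limma_fixture, method="welch")
    L = np.log2(limma_fixture.values.values + 1)
    _, p = __import__("scipy.stats", fromlist=["ttest_ind"]).ttest_ind(
        L[:, :5], L[:, 5:], axis=1, equal_var=False)
    np.testing.assert_allclose(de["p_value"], p, atol=1e-12)


def test_unknown_method_rejected(limma_fixture):
    with pytest.raises(ValueError, match="method"):
        rt.differential_expression(limma_fixture, method="bogus")


def test_fold_change_closed_form():
    vals = np.array([[10.0, 10, 10, 2.0, 2, 2]])
    de = rt.differential_expression(_make_expr(vals, 3, 3))
    assert de["fold_change"].iloc[0] == pytest.approx(5.0)
    assert de["log2fc"].iloc[0] == pytest.approx(np.log2(5), abs=1e-4)


def test_identical_groups_give_null_result():
    vals = np.tile([[4.0, 7.0, 5.0]], (1, 2))
    de = rt.differential_expression(_make_expr(vals, 3, 3))
    assert de["log2fc"].iloc[0] == 0
    assert de["p_value"].iloc[0] == pytest.approx(1.0)


def test_zero_in_both_groups_flagged():
    vals = np.vstack([np.zeros(6), [9, 8, 7, 1, 1, 2]])
    de = rt.differential_expression(_make_expr(vals, 3, 3))
    assert bool(de["zero_both"].iloc[0])
    assert de["log2fc"].iloc[0] == 0
    labels = rt.assign_labels(de)
    assert labels.iloc[0] == "excluded_fdr"


def test_too_few_samples_rejected():
    with pytest.raises(ValueError):
        rt.differential_expression(_make_expr(np.ones((2, 3)), 1, 2))


def test_bh_spec_example():
    np.testing.assert_allclose(bh_stepup([0.01, 0.02, 0.03, 0.8]),
                               [0.04, 0.04, 0.04, 0.8])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=100))
def test_bh_matches_hand_stepup_oracle(pvec):
    """The BH adjustment used by the pipeline equals the brute-force
    step-up pass on arbitrary p-vectors."""
    from statsmodels.stats.multitest import multipletests
    _, fdr, _, _ = multipletests(pvec, method="fdr_bh")
    np.testing.assert_allclose(fdr, bh_stepup(pvec), atol=1e-12)


def _label_of(log2fc, fdr, pseudo=()):
    de = pd.DataFrame({"log2fc": [log2fc], "fdr": [fdr],
                       "zero_both": [False]}, index=["g"])
    return rt.assign_labels(de, pseudo).iloc[0]


@pytest.mark.parametrize("log2fc,fdr,expected", [
    (2.5, 0.01, "positive_up"),
    (-2.5, 0.01, "positive_down"),
    (2.5, 0.05, "excluded_fdr"),     # FDR >= 0.05 excludes at equality
    (1.0, 0.001, "ambiguous"),
    (2.0, 0.01, "ambiguous"),        # strict > 2 fails at equality
    (-2.0, 0.01, "ambiguous"),
    (0.3, 0.01, "ambiguous"),        # strict |log2FC| < 0.3 for negatives
    (-0.3, 0.01, "ambiguous"),
    (0.29, 0.01, "negative"),
    (0.0, 0.01, "negative"),
    (2.5, 0.049999, "positive_up"),
])
def test_label_rules_and_boundaries(log2fc, fdr, expected):
    assert _label_of(log2fc, fdr) == expected


def test_pseudogene_exclusion_only_for_would_be_positives():
    assert _label_of(3.0, 0.01, pseudo={"g"}) == "excluded_pseudogene"
    assert _label_of(0.1, 0.01, pseudo={"g"}) == "negative"
    assert _label_of(3.0, 0.5, pseudo={"g"}) == "excluded_fdr"


def test_missing_pseudogene_warns():
    de = pd.DataFrame({"log2fc": [1.0], "fdr": [0.01], "zero_both": [False]},
                      index=["g"])
    with pytest.warns(UserWarning):
        rt.assign_labels(de, {"absent_gene"})


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.lists(st.tuples(st.floats(-5, 5, allow_nan=False),
                          st.floats(0, 1, allow_nan=False)),
                min_size=1, max_size=60))
def test_labels_partition_every_gene(rows):
    de = pd.DataFrame(rows, columns=["log2fc", "fdr"],
                      index=[f"g{i}" for i in range(len(rows))])
    de["zero_both"] = False
    labels = rt.assign_labels(de)
    assert len(labels) == len(de)
    assert set(labels.unique()) <= set(rt.de.LABELS)


def test_label_monotone_in_fold_change():
    """With FDR fixed below 0.05, increasing |log2FC| never demotes a
    positive gene."""
    fcs = np.linspace(0, 5, 200)
    labels = [_label_of(f, 0.01) for f in fcs]
    seen_positive = False
    for lab in labels:
        if lab == "positive_up":
            seen_positive = True
        elif seen_positive:
            pytest.fail("gene left the positive class as log2FC increased")
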