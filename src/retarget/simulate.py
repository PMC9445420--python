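"""Seeded synthetic inputs for the gene-prioritization / repositioning pipeline.

Emulates the statistical structure of the real study inputs — a
tumor/normal FPKM expression matrix with planted differential genes, a
functional-annotation score table informative for disease genes, a
scale-free weighted interaction graph with label homophily, and
drug-target sets of which a planted subset lives inside the disease
neighbourhood — together with the ground truth needed for recovery
tests.

Truth classes per gene:

``up`` / ``down``
    strong planted differential expression (|log2FC| = ``planted_log2fc``),
    disease-like annotation features, homophilous edges.
``hidden``
    disease-like features and edges but an expression effect inside the
    ambiguous fold-change band, so the DE labeler cannot call it — the
    genes the graph classifier is meant to rescue.
``null``
    essentially unchanged expression (true log2FC jittered uniformly in
    ±``null_log2fc_jitter``; exactly zero when the jitter is 0), noise
    features.
``background``
    intermediate expression effects in (0.3, 2) in absolute log2FC, so
    they land in the ambiguous partition; noise features.

One master seed drives independent child streams (via
``numpy.random.SeedSequence.spawn`` ordering), so adding a generator
never perturbs the output of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig", "SyntheticTruth", "ExpressionMatrix", "FeatureTable",
    "simulate_expression", "simulate_annotation_features", "simulate_graph",
    "simulate_drugs", "simulate_all",
]


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic generators (desk scale)."""

    n_genes: int = 2000
    n_tumor: int = 60
    n_normal: int = 60
    frac_up: float = 0.03
    frac_down: float = 0.03
    frac_null: float = 0.30
    frac_hidden: float = 0.02
    planted_log2fc: float = 3.0
    null_log2fc_jitter: float = 0.25
    dispersion: float = 0.25          # SD of multiplicative log-normal noise (ln scale)
    baseline_log_mean: float = 3.0    # ln of typical baseline FPKM
    baseline_log_sd: float = 1.0
    n_features: int = 100
    n_informative_features: int = 20
    feature_shift: float = 2.0        # mean -log10(p) uplift for disease genes
    feature_missing_rate: float = 0.10
    n_high_missing_features: int = 5
    high_missing_rate: float = 0.60
    n_duplicate_features: int = 6
    feature_block_corr: float = 0.99
    graph_attachment: int = 2
    homophily_boost: float = 4.0
    unweighted_edge_fraction: float = 0.10
    n_drugs: int = 200
    n_planted_drugs: int = 5
    targets_per_drug: int = 10
    decoy_low_ic50_fraction: float = 0.2
    seed: int = 0

    def validate(self):
        counts = dict(n_genes=self.n_genes, n_tumor=self.n_tumor,
                      n_normal=self.n_normal, n_features=self.n_features,
                      n_drugs=self.n_drugs, targets_per_drug=self.targets_per_drug,
                      graph_attachment=self.graph_attachment)
        for name, v in counts.items():
            if int(v) < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        fracs = (self.frac_up, self.frac_down, self.frac_null, self.frac_hidden)
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("class fractions must be non-negative and sum to <= 1")
        if not (0 <= self.feature_missing_rate < 1):
            raise ValueError("feature_missing_rate must be in [0, 1)")
        if not (0 <= self.feature_block_corr <= 1):
            raise ValueError("feature_block_corr must be in [0, 1]")
        if self.homophily_boost < 1:
            raise ValueError("homophily_boost must be >= 1")
        if self.n_planted_drugs > self.n_drugs:
            raise ValueError("n_planted_drugs must be <= n_drugs")
        if self.n_informative_features > self.n_features:
            raise ValueError("n_informative_features must be <= n_features")
        if self.graph_attachment >= self.n_genes:
            raise ValueError("graph_attachment must be < n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child generator: stream index keys the substream."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


# fixed substream indices — append-only so new generators never shift old ones
_STREAM_TRUTH = 0
_STREAM_EXPR = 1
_STREAM_FEATURES = 2
_STREAM_GRAPH = 3
_STREAM_DRUGS = 4


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene class and the proximal drug ids."""

    gene_truth: dict[str, str]
    true_log2fc: dict[str, float] = field(default_factory=dict)
    informative_features: list[str] = field(default_factory=list)
    planted_drugs: set[str] = field(default_factory=set)

    def disease_genes(self) -> set[str]:
        return {g for g, t in self.gene_truth.items()
                if t in ("up", "down", "hidden")}

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"gene_truth": self.gene_truth,
                       "true_log2fc": self.true_log2fc,
                       "informative_features": self.informative_features,
                       "planted_drugs": sorted(self.planted_drugs)}, fh, indent=1)


@dataclass
class ExpressionMatrix:
    """FPKM-like values (genes x samples) plus tumor/normal group labels."""

    values: pd.DataFrame
    groups: pd.Series  # sample id -> {"tumor", "normal"}

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class FeatureTable:
    """Annotation scores (-log10 p semantics); NaN marks missing entries."""

    matrix: pd.DataFrame

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.matrix.isna()


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _assign_truth(config: SimulationConfig) -> tuple[dict, dict]:
    """Shuffled truth assignment and true per-gene log2FC."""
    rng = config.rng(_STREAM_TRUTH)
    genes = _gene_ids(config.n_genes)
    order = rng.permutation(config.n_genes)
    n_up = int(round(config.frac_up * config.n_genes))
    n_down = int(round(config.frac_down * config.n_genes))
    n_null = int(round(config.frac_null * config.n_genes))
    n_hidden = int(round(config.frac_hidden * config.n_genes))
    truth, l2fc = {}, {}
    pos = 0
    for cls, count in (("up", n_up), ("down", n_down), ("null", n_null),
                       ("hidden", n_hidden)):
        for i in order[pos:pos + count]:
            truth[genes[i]] = cls
        pos += count
    for i in order[pos:]:
        truth[genes[i]] = "background"
    for g in genes:
        t = truth[g]
        if t == "up":
            l2fc[g] = config.planted_log2fc
        elif t == "down":
            l2fc[g] = -config.planted_log2fc
        elif t == "null":
            l2fc[g] = float(rng.uniform(-config.null_log2fc_jitter,
                                        config.null_log2fc_jitter))
        elif t == "hidden":
            mag = rng.uniform(0.5, 1.5)
            l2fc[g] = float(mag * rng.choice([-1.0, 1.0]))
        else:  # background: ambiguous band, |log2FC| in (0.3, 2)
            mag = rng.uniform(0.3, 2.0)
            l2fc[g] = float(mag * rng.choice([-1.0, 1.0]))
    return truth, l2fc


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-group log-normal expression with planted fold changes.

    Per gene g with baseline mean m_g, tumor samples draw
    m_g * 2^(fc/2) * exp(sigma Z) and normal samples the reciprocal
    half-effect, so E[tumor]/E[normal] = 2^fc exactly.
    """
    config.validate()
    truth_map, l2fc = _assign_truth(config)
    rng = config.rng(_STREAM_EXPR)
    genes = _gene_ids(config.n_genes)
    baseline = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sd, config.n_genes))
    fc = np.array([l2fc[g] for g in genes])
    mean_t = baseline * np.power(2.0, fc / 2.0)
    mean_n = baseline * np.power(2.0, -fc / 2.0)
    noise_t = np.exp(config.dispersion
                     * rng.standard_normal((config.n_genes, config.n_tumor)))
    noise_n = np.exp(config.dispersion
                     * rng.standard_normal((config.n_genes, config.n_normal)))
    vals = np.hstack([mean_t[:, None] * noise_t, mean_n[:, None] * noise_n])
    samples = ([f"T{i:03d}" for i in range(config.n_tumor)]
               + [f"N{i:03d}" for i in range(config.n_normal)])
    groups = pd.Series(["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
                       index=samples, name="group")
    expr = ExpressionMatrix(values=pd.DataFrame(vals, index=genes, columns=samples),
                            groups=groups)
    truth = SyntheticTruth(gene_truth=truth_map, true_log2fc=l2fc)
    return expr, truth


def simulate_annotation_features(config: SimulationConfig,
                                 truth: SyntheticTruth) -> FeatureTable:
    """Non-negative annotation scores with informative, duplicated and
    high-missingness columns, so every downstream filter has work to do."""
    config.validate()
    rng = config.rng(_STREAM_FEATURES)
    genes = _gene_ids(config.n_genes)
    disease = np.array([truth.gene_truth[g] in ("up", "down", "hidden")
                        for g in genes])
    n_base = config.n_features - config.n_duplicate_features
    if n_base < config.n_informative_features:
        raise ValueError("too many duplicate features for n_features")
    cols, names = [], []
    for j in range(n_base):
        base = rng.exponential(1.0, config.n_genes)
        if j < config.n_informative_features:
            base = base + disease * rng.gamma(2.0, config.feature_shift / 2.0,
                                              config.n_genes)
        cols.append(base)
        names.append(f"feat_{j:03d}")
    # near-duplicate block: y = x + eta*sd(x)*N(0,1) gives corr ~ rho
    rho = config.feature_block_corr
    eta = np.sqrt(max(1.0 - rho ** 2, 0.0)) / max(rho, 1e-6)
    for j in range(config.n_duplicate_features):
        srcj = j % max(n_base, 1)
        x = cols[srcj]
        y = x + eta * x.std() * rng.standard_normal(config.n_genes)
        cols.append(np.clip(y, 0.0, None))
        names.append(f"feat_dup_{j:03d}")
    mat = np.column_stack(cols)
    miss = rng.random(mat.shape) < config.feature_missing_rate
    # a few columns with heavy missingness to exercise the 40% filter
    high = rng.choice(n_base, size=min(config.n_high_missing_features, n_base),
                      replace=False)
    for j in high:
        miss[:, j] |= rng.random(config.n_genes) < config.high_missing_rate
    mat = mat.astype(float)
    mat[miss] = np.nan
    df = pd.DataFrame(mat, index=genes, columns=names)
    truth.informative_features = names[:config.n_informative_features]
    return FeatureTable(matrix=df)


def simulate_graph(config: SimulationConfig, truth: SyntheticTruth) -> nx.Graph:
    """Connected scale-free interaction graph with label homophily.

    Preferential attachment gives the heavy-tailed degree distribution;
    homophily_boost > 1 multiplies disease-disease edge weights by the
    boost AND adds (boost - 1) * n_disease extra disease-disease edges,
    so that the homophily signal is both topological and weighted. A
    configurable fraction of edges is emitted weightless (weight None)
    to exercise mean-weight imputation downstream.
    """
    config.validate()
    rng = config.rng(_STREAM_GRAPH)
    genes = _gene_ids(config.n_genes)
    ba = nx.barabasi_albert_graph(config.n_genes, config.graph_attachment,
                                  seed=int(rng.integers(2 ** 31)))
    perm = rng.permutation(config.n_genes)
    mapping = {i: genes[perm[i]] for i in range(config.n_genes)}
    g = nx.relabel_nodes(ba, mapping)
    disease = truth.disease_genes()
    for u, v in g.edges():
        w = float(rng.uniform(0.2, 1.0))
        if u in disease and v in disease:
            w *= config.homophily_boost
        g[u][v]["weight"] = w
    n_extra = int(round((config.homophily_boost - 1.0) * len(disease)))
    dlist = sorted(disease)
    added = 0
    while added < n_extra and len(dlist) >= 2:
        u, v = rng.choice(len(dlist), size=2, replace=False)
        u, v = dlist[u], dlist[v]
        if g.has_edge(u, v):
            added += 1  # count attempts so dense disease sets terminate
            continue
        g.add_edge(u, v, weight=float(rng.uniform(0.2, 1.0)) * config.homophily_boost)
        added += 1
    if config.unweighted_edge_fraction > 0:
        edges = list(g.edges())
        k = int(round(config.unweighted_edge_fraction * len(edges)))
        for i in rng.choice(len(edges), size=k, replace=False):
            u, v = edges[i]
            g[u][v]["weight"] = None
    return g


def simulate_drugs(config: SimulationConfig, truth: SyntheticTruth,
                   graph: nx.Graph) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Drug-target sets plus an IC50 table.

    Planted drugs sample their targets from the disease core, so their
    expanded target networks (targets plus first neighbours) lie inside
    the disease network — strongly proximal by construction; decoys
    sample uniformly from all genes. Planted (drug, target) pairs get
    median IC50 below 10,000 nM; a configurable fraction of decoy pairs
    is also sub-threshold, the rest above it.
    """
    config.validate()
    rng = config.rng(_STREAM_DRUGS)
    genes = _gene_ids(config.n_genes)
    pool = sorted(truth.disease_genes())
    drug_ids = [f"drug_{i:03d}" for i in range(config.n_drugs)]
    planted = set(rng.choice(drug_ids, size=config.n_planted_drugs,
                             replace=False).tolist())
    targets: dict[str, set[str]] = {}
    rows = []
    for d in drug_ids:
        if d in planted:
            k = min(config.targets_per_drug, len(pool))
            tg = set(rng.choice(pool, size=k, replace=False).tolist())
        else:
            tg = set(rng.choice(genes, size=min(config.targets_per_drug,
                                                len(genes)),
                                replace=False).tolist())
        targets[d] = tg
        for t in sorted(tg):
            if d in planted:
                ic50 = 10.0 ** rng.uniform(1.0, 3.7)       # 10 nM .. ~5 uM
            elif rng.random() < config.decoy_low_ic50_fraction:
                ic50 = 10.0 ** rng.uniform(1.0, 3.7)
            else:
                ic50 = 10.0 ** rng.uniform(4.1, 6.0)       # clearly above 10 uM
            rows.append((d, t, float(ic50)))
    truth.planted_drugs = planted
    ic50_table = pd.DataFrame(rows, columns=["drug", "target_gene",
                                             "median_ic50_nM"])
    return targets, ic50_table


def simulate_all(config: SimulationConfig):
    """Run all four generators; returns (expr, features, graph, drugs, ic50, truth)."""
    expr, truth = simulate_expression(config)
    feats = simulate_annotation_features(config, truth)
    graph = simulate_graph(config, truth)
    drugs, ic50 = simulate_drugs(config, truth, graph)
    return expr, feats, graph, drugs, ic50, truth


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
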