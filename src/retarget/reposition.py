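"""Network-proximity drug repositioning.

Three statistics per drug, computed between the disease gene network
N_g (disease genes plus first graph neighbours) and the drug network
N_di (targets plus first neighbours):

* Jaccard overlap  J = |N_g ∩ N_di| / (|N_g| + |N_di| − |N_g ∩ N_di|)
* closest network distance
      d(N_g, N_di) = (1/|N_di'|) Σ_{g ∈ N_di'} min_{s ∈ N_g} sp(g, s)
  over the drug genes N_di' with a finite path to the disease set
  (hop-count shortest paths; shared genes contribute 0)
* permutation z-score  z = (d − μ) / σ against a null of random
  (optionally degree-matched, log2-degree bins) pseudo-target sets of
  the same size, expanded to their own first-neighbour networks.

Summary filter: Jaccard strictly above the all-drug mean, z strictly
below −2, and overlap fraction |N_g ∩ N_di| / |N_di| of at least 0.5.
A physical-interaction filter keeps drug-target pairs with median IC50
strictly below 10,000 nM whose target is among the predicted genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netgraph import neighborhood

__all__ = ["jaccard_score", "closest_distance", "distance_field",
           "proximity_null", "z_score", "summarize", "ic50_filter",
           "ProximityNull", "DrugProximityModel", "RepositioningResults"]

log = logging.getLogger(__name__)


def jaccard_score(ng, ndi) -> float:
    """Intersection over union of two gene sets."""
    ng, ndi = set(ng), set(ndi)
    if not ng and not ndi:
        raise ValueError("Jaccard undefined: both sets empty")
    inter = len(ng & ndi)
    return inter / (len(ng) + len(ndi) - inter)


def distance_field(graph: nx.Graph, ng) -> dict:
    """Hop distance from every reachable node to its nearest disease gene.

    One multi-source BFS from N_g; nodes with no finite path are absent
    from the returned dict.
    """
    sources = set(ng) & set(graph.nodes)
    if not sources:
        raise ValueError("no disease genes present in the graph")
    dist = {s: 0 for s in sources}
    frontier = list(sources)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def closest_distance(ng, ndi, graph: nx.Graph, _field: dict | None = None,
                     min_reachable: float = 0.5) -> tuple[float, float]:
    """Average over drug-network genes of the distance to the nearest
    disease gene; returns (distance, reachable_fraction).

    Unreachable drug genes are dropped from the average; when fewer than
    ``min_reachable`` of N_di reach the disease set the distance is NaN
    (drug unscoreable).
    """
    ndi = set(ndi)
    if not ndi:
        raise ValueError("empty drug network")
    field = _field if _field is not None else distance_field(graph, ng)
    # sorted iteration: float summation order independent of set hashing
    vals = [field[g] for g in sorted(ndi, key=str) if g in field]
    frac = len(vals) / len(ndi)
    if not vals or frac < min_reachable:
        return float("nan"), frac
    return float(np.mean(vals)), frac


@dataclass
class ProximityNull:
    """Permutation null of closest distances for one drug."""

    n_perm: int
    mu: float
    sigma: float
    null_samples: np.ndarray
    seed: int

    @property
    def degenerate(self) -> bool:
        return not (self.sigma > 0)


def _degree_bins(graph: nx.Graph) -> dict:
    """log2-degree bins -> numpy array of member nodes."""
    bins: dict[int, list] = {}
    for n, deg in graph.degree():
        b = int(np.floor(np.log2(deg))) if deg > 0 else -1
        bins.setdefault(b, []).append(n)
    return {b: np.array(sorted(v), dtype=object) for b, v in bins.items()}


def proximity_null(targets_size: int, ng, graph: nx.Graph, n_perm: int = 1000,
                   seed: int = 0, degree_matched: bool = True,
                   targets=None, _field: dict | None = None,
                   _bins: dict | None = None) -> ProximityNull:
    """Null distribution of closest distances from random pseudo-drugs.

    Each permutation draws ``targets_size`` distinct graph nodes —
    uniformly, or degree-binned against the real ``targets`` (log2
    bins) when ``degree_matched`` — expands them to their
    first-neighbour network and scores it with the same closest-distance
    measure. μ and σ are the sample mean and standard deviation.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    field = _field if _field is not None else distance_field(graph, ng)
    nodes = np.array(sorted(graph.nodes), dtype=object)
    if degree_matched:
        if targets is None:
            raise ValueError("degree_matched sampling needs the real targets")
        bins = _bins if _bins is not None else _degree_bins(graph)
        tbins = []
        for t in sorted(targets, key=str):
            if t in graph:
                deg = graph.degree(t)
                tbins.append(int(np.floor(np.log2(deg))) if deg > 0 else -1)
        while len(tbins) < targets_size:
            tbins.append(-1 if -1 in bins else min(bins))
        tbins = tbins[:targets_size]
    samples = np.empty(n_perm)
    adj = {n: np.array(list(graph.neighbors(n)), dtype=object)
           for n in graph.nodes}
    for i in range(n_perm):
        chosen: set = set()
        if degree_matched:
            for b in tbins:
                pool = bins.get(b, nodes)
                for _ in range(50):
                    cand = pool[rng.integers(len(pool))]
                    if cand not in chosen:
                        break
                chosen.add(cand)
        else:
            idx = rng.choice(len(nodes), size=min(targets_size, len(nodes)),
                             replace=False)
            chosen = set(nodes[idx])
        ndi = set(chosen)
        for c in chosen:
            ndi.update(adj[c])
        vals = [field[g] for g in sorted(ndi, key=str) if g in field]
        samples[i] = np.mean(vals) if vals else np.nan
    samples = samples[~np.isnan(samples)]
    mu = float(samples.mean())
    sigma = float(samples.std(ddof=1)) if len(samples) > 1 else 0.0
    return ProximityNull(n_perm=n_perm, mu=mu, sigma=sigma,
                         null_samples=samples, seed=seed)


def z_score(d: float, null: ProximityNull) -> float:
    """(d − μ) / σ; NaN (flagged) when the null is degenerate."""
    if null.degenerate or not np.isfinite(d):
        return float("nan")
    return (d - null.mu) / null.sigma


def summarize(scores: pd.DataFrame) -> pd.DataFrame:
    """Apply the summary filter and rank the passers.

    Expects columns jaccard, z, overlap_fraction. The mean Jaccard is
    taken over all scored (finite-z) drugs; passers have Jaccard
    strictly above it, z strictly below −2 and overlap fraction ≥ 0.5.
    Output is the passers sorted by Jaccard descending.
    """
    scored = scores[np.isfinite(scores["z"])]
    mean_j = float(scored["jaccard"].mean()) if len(scored) else float("nan")
    passes = (
        (scored["jaccard"] > mean_j)
        & (scored["z"] < -2)
        & (scored["overlap_fraction"] >= 0.5)
    )
    out = scored[passes].sort_values("jaccard", ascending=False).copy()
    out.attrs["mean_jaccard"] = mean_j
    return out


def ic50_filter(pairs: pd.DataFrame, predicted_genes,
                threshold: float = 10_000.0) -> pd.DataFrame:
    """Physical-interaction filter: median IC50 strictly below the
    threshold (nM) and target gene among the predicted genes."""
    predicted_genes = set(predicted_genes)
    ic50 = pairs["median_ic50_nM"].astype(float)
    keep = (ic50 < threshold) & pairs["target_gene"].isin(predicted_genes)
    return pairs[keep].reset_index(drop=True)


class DrugProximityModel:
    """Network-proximity repositioning model.

    Parameters
    ----------
    graph : networkx.Graph
        Background interaction graph (weights are ignored: proximity
        uses hop counts).
    disease_genes : set
        The disease gene list — conventionally DE positives plus the
        classifier's predicted genes.
    drug_targets : dict
        Drug id -> set of target gene symbols.
    include_neighbors : bool
        Expand both gene lists to their first-neighbour networks
        (default, matching the network construction rule).
    """

    def __init__(self, graph: nx.Graph, disease_genes, drug_targets: dict,
                 include_neighbors: bool = True):
        self.graph = graph
        self.disease_genes = set(disease_genes)
        self.drug_targets = {d: set(t) for d, t in drug_targets.items()}
        self.include_neighbors = include_neighbors
        self.ng = neighborhood(graph, self.disease_genes, include_neighbors)
        if not self.ng:
            raise ValueError("disease network is empty")
        self._field = distance_field(graph, self.ng)

    def fit(self, n_perm: int = 1000, seed: int = 0,
            degree_matched: bool = True) -> "RepositioningResults":
        bins = _degree_bins(self.graph) if degree_matched else None
        rows = []
        nulls = {}
        seeds = np.random.SeedSequence(seed).spawn(len(self.drug_targets))
        for (drug, targets), ss in zip(sorted(self.drug_targets.items()), seeds):
            tg = targets & set(self.graph.nodes)
            if not tg:
                log.info("drug %s has no targets in the graph; unscoreable", drug)
                rows.append({"drug": drug, "n_targets": len(targets),
                             "n_targets_in_graph": 0, "jaccard": np.nan,
                             "distance": np.nan, "mu": np.nan, "sigma": np.nan,
                             "z": np.nan, "overlap_fraction": np.nan,
                             "scoreable": False})
                continue
            ndi = neighborhood(self.graph, tg, self.include_neighbors)
            j = jaccard_score(self.ng, ndi)
            d, reach = closest_distance(self.ng, ndi, self.graph,
                                        _field=self._field)
            null = proximity_null(len(tg), self.ng, self.graph, n_perm=n_perm,
                                  seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                                  degree_matched=degree_matched, targets=tg,
                                  _field=self._field, _bins=bins)
            z = z_score(d, null)
            nulls[drug] = null
            overlap = len(self.ng & ndi) / len(ndi)
            rows.append({"drug": drug, "n_targets": len(targets),
                         "n_targets_in_graph": len(tg), "jaccard": j,
                         "distance": d, "mu": null.mu, "sigma": null.sigma,
                         "z": z, "overlap_fraction": overlap,
                         "scoreable": bool(np.isfinite(d) and np.isfinite(z))})
        scores = pd.DataFrame(rows).set_index("drug")
        return RepositioningResults(model=self, scores=scores, nulls=nulls,
                                    n_perm=n_perm, seed=seed)


@dataclass
class RepositioningResults:
    """Per-drug proximity statistics and the summary filter."""

    model: DrugProximityModel
    scores: pd.DataFrame
    nulls: dict
    n_perm: int
    seed: int
    _passers: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def mean_jaccard(self) -> float:
        scored = self.scores[self.scores["scoreable"]]
        return float(scored["jaccard"].mean())

    def passers(self) -> pd.DataFrame:
        if self._passers is None:
            scored = self.scores[self.scores["scoreable"]]
            self._passers = summarize(scored)
        return self._passers

    def with_summary_flag(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["passes_summary"] = out.index.isin(self.passers().index)
        return out

    def ic50_filter(self, pairs: pd.DataFrame, predicted_genes=None,
                    threshold: float = 10_000.0) -> pd.DataFrame:
        genes = (self.model.disease_genes if predicted_genes is None
                 else predicted_genes)
        return ic50_filter(pairs, genes, threshold)

    def plot_z_distribution(self, ax=None):
        import matplotlib.pyplot as plt

        z = self.scores.loc[self.scores["scoreable"], "z"]
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(z, bins=30)
        ax.axvline(-2, color="red", ls="--", label="z = -2")
        ax.set_xlabel("proximity z-score")
        ax.set_ylabel("drugs")
        ax.legend()
        return ax

    def summary(self) -> str:
        p = self.passers()
        scored = self.scores[self.scores["scoreable"]]
        lines = [
            "Network-proximity drug repositioning",
            "=" * 45,
            f"drugs scored: {len(scored)} / {len(self.scores)}   "
            f"permutations: {self.n_perm}",
            f"disease network size |N_g|: {len(self.model.ng)}",
            f"mean Jaccard: {self.mean_jaccard:.4f}",
            f"drugs with z < -2: {int((scored['z'] < -2).sum())}",
            f"summary-filter passers: {len(p)}",
        ]
        if len(p):
            lines.append("")
            lines.append(p[["jaccard", "z", "overlap_fraction"]]
                         .round(3).to_string())
        return "\n".join(lines)
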