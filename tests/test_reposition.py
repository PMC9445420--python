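"""Proximity scoring: Jaccard, closest distance, permutation null, filters."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import retarget as rt
from retarget.examples import (luad_candidate_drugs, luad_ic50_pairs,
                               LUAD_ALL_DRUG_MEAN_JACCARD)
from retarget.reposition import ProximityNull, distance_field


class TestJaccard:
    def test_identical_sets(self):
        assert rt.jaccard_score({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert rt.jaccard_score({"a"}, {"b"}) == 0.0

    def test_direct_formula(self):
        ng = {"a", "b", "c", "d"}
        ndi = {"c", "d", "e", "f"}
        assert rt.jaccard_score(ng, ndi) == pytest.approx(2 / 6)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            rt.jaccard_score(set(), set())

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_matches_set_arithmetic_oracle(self, a, b):
        if not a and not b:
            return
        expected = len(a & b) / len(a | b)  # independent formulation
        assert rt.jaccard_score(a, b) == pytest.approx(expected)
        assert rt.jaccard_score(b, a) == pytest.approx(expected)  # symmetry
        assert 0 <= expected <= 1
        assert (expected == 1.0) == (a == b)


class TestClosestDistance:
    def test_subset_gives_zero(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        d, frac = rt.closest_distance({"a", "b", "c"}, {"b", "c"}, g)
        assert d == 0.0 and frac == 1.0

    def test_path_graph_examples(self):
        g = nx.path_graph(["a", "b", "c"])
        d, _ = rt.closest_distance({"a"}, {"c"}, g)
        assert d == 2.0
        d, _ = rt.closest_distance({"a", "c"}, {"b", "c"}, g)
        assert d == 0.5

    def test_unreachable_drug_flagged(self):
        g = nx.Graph([("a", "b")])
        g.add_node("x")
        d, frac = rt.closest_distance({"a"}, {"x"}, g)
        assert np.isnan(d) and frac == 0.0

    def test_matches_all_pairs_bfs_oracle(self):
        """Exhaustive check against networkx all-pairs BFS on 100 random
        graphs of up to 30 nodes."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2 ** 31)))
            nodes = list(g.nodes)
            ng = set(rng.choice(nodes, size=int(rng.integers(1, max(2, n // 3))),
                                replace=False).tolist())
            ndi = set(rng.choice(nodes, size=int(rng.integers(1, max(2, n // 3))),
                                 replace=False).tolist())
            sp = dict(nx.all_pairs_shortest_path_length(g))
            vals = []
            for t in ndi:
                finite = [sp[t][s] for s in ng if s in sp[t]]
                if finite:
                    vals.append(min(finite))
            frac = len(vals) / len(ndi)
            d, got_frac = rt.closest_distance(ng, ndi, g, min_reachable=0.0)
            assert got_frac == pytest.approx(frac)
            if vals:
                assert d == pytest.approx(float(np.mean(vals)))
            else:
                assert np.isnan(d)

    def test_distance_of_set_to_itself_is_zero(self):
        g = nx.cycle_graph(list("abcdef"))
        d, _ = rt.closest_distance({"a", "c"}, {"a", "c"}, g)
        assert d == 0.0

    def test_shared_gene_monotonicity(self):
        """Adding one shared gene never lowers Jaccard nor raises distance."""
        rng = np.random.default_rng(12)
        g = nx.gnp_random_graph(25, 0.2, seed=3)
        nodes = list(g.nodes)
        for _ in range(20):
            ng = set(rng.choice(nodes, size=5, replace=False).tolist())
            ndi = set(rng.choice(nodes, size=5, replace=False).tolist())
            extra = [x for x in nodes if x not in ng and x not in ndi]
            if not extra:
                continue
            s = extra[0]
            j0 = rt.jaccard_score(ng, ndi)
            d0, _ = rt.closest_distance(ng, ndi, g, min_reachable=0.0)
            j1 = rt.jaccard_score(ng | {s}, ndi | {s})
            d1, _ = rt.closest_distance(ng | {s}, ndi | {s}, g,
                                        min_reachable=0.0)
            assert j1 >= j0 - 1e-12
            if np.isfinite(d0) and np.isfinite(d1):
                assert d1 <= d0 + 1e-12


class TestNull:
    def test_null_moments_are_sample_moments(self):
        g = nx.barabasi_albert_graph(100, 2, seed=0)
        null = rt.proximity_null(4, set(range(10)), g, n_perm=50, seed=5,
                                 degree_matched=False)
        assert null.mu == pytest.approx(null.null_samples.mean())
        assert null.sigma == pytest.approx(null.null_samples.std(ddof=1))

    def test_sample_sd_convention(self):
        null = ProximityNull(n_perm=2, mu=2.0, sigma=float(np.std([1, 3], ddof=1)),
                             null_samples=np.array([1.0, 3.0]), seed=0)
        assert null.sigma == pytest.approx(np.sqrt(2))

    def test_deterministic_under_seed(self):
        g = nx.barabasi_albert_graph(80, 2, seed=1)
        a = rt.proximity_null(3, set(range(8)), g, n_perm=30, seed=9,
                              degree_matched=True, targets={0, 1, 2})
        b = rt.proximity_null(3, set(range(8)), g, n_perm=30, seed=9,
                              degree_matched=True, targets={0, 1, 2})
        np.testing.assert_array_equal(a.null_samples, b.null_samples)

    def test_too_few_permutations_rejected(self):
        g = nx.path_graph(5)
        with pytest.raises(ValueError):
            rt.proximity_null(2, {0}, g, n_perm=1, seed=0,
                              degree_matched=False)


class TestZScore:
    def _null(self, mu, sigma):
        return ProximityNull(n_perm=10, mu=mu, sigma=sigma,
                             null_samples=np.array([]), seed=0)

    def test_at_mean_is_zero(self):
        assert rt.z_score(1.5, self._null(1.5, 0.3)) == 0.0

    def test_two_sigma_below(self):
        assert rt.z_score(0.9, self._null(1.5, 0.3)) == pytest.approx(-2.0)

    def test_degenerate_sigma_flagged(self):
        assert np.isnan(rt.z_score(1.0, self._null(1.0, 0.0)))


class TestSummary:
    def test_published_candidates_all_pass(self):
        """The ten reported (Jaccard, z) pairs all clear the summary rule
        against the reported all-drug mean Jaccard."""
        tab = luad_candidate_drugs()
        passes = ((tab["jaccard"] > LUAD_ALL_DRUG_MEAN_JACCARD)
                  & (tab["z"] < -2) & (tab["overlap_fraction"] >= 0.5))
        assert passes.all() and len(tab) == 10

    def test_z_above_minus_two_fails_regardless_of_jaccard(self):
        df = pd.DataFrame({"jaccard": [0.9, 0.95, 0.01], "z": [-1.5, -3.0, -3.0],
                           "overlap_fraction": [1.0, 1.0, 1.0]})
        out = rt.summarize(df)
        assert list(out.index) == [1]  # 0 fails on z despite high Jaccard

    def test_overlap_boundary_049_excluded(self):
        df = pd.DataFrame({"jaccard": [0.5, 0.01], "z": [-3.0, -3.0],
                           "overlap_fraction": [0.49, 0.9]})
        out = rt.summarize(df)
        assert 0 not in out.index

    def test_output_sorted_by_jaccard_descending(self):
        df = pd.DataFrame({"jaccard": [0.2, 0.5, 0.4, 0.001],
                           "z": [-3.0, -3.0, -3.0, -3.0],
                           "overlap_fraction": [1.0, 1.0, 1.0, 1.0]})
        out = rt.summarize(df)
        assert list(out["jaccard"]) == sorted(out["jaccard"], reverse=True)


class TestIC50:
    def test_published_pairs_all_physical(self):
        pairs = luad_ic50_pairs()
        out = rt.ic50_filter(pairs, set(pairs["target_gene"]))
        assert len(out) == 14

    def test_exact_threshold_excluded(self):
        pairs = pd.DataFrame({"drug": ["d"], "target_gene": ["g"],
                              "median_ic50_nM": [10_000.0]})
        assert rt.ic50_filter(pairs, {"g"}).empty

    def test_empty_predicted_genes_empty_output(self):
        pairs = luad_ic50_pairs()
        assert rt.ic50_filter(pairs, set()).empty


class TestModel:
    def test_fit_scores_every_drug(self, small_sim):
        _, _, graph, drugs, _, truth = small_sim
        g = rt.impute_unweighted_edges(graph)
        model = rt.DrugProximityModel(g, truth.disease_genes(), drugs)
        res = model.fit(n_perm=50, seed=0)
        assert len(res.scores) == len(drugs)
        scored = res.scores[res.scores["scoreable"]]
        assert ((scored["jaccard"] >= 0) & (scored["jaccard"] <= 1)).all()
        assert ((scored["overlap_fraction"] >= 0)
                & (scored["overlap_fraction"] <= 1)).all()

    def test_distance_field_matches_bfs(self, small_sim):
        graph = small_sim[2]
        ng = set(list(graph.nodes)[:10])
        field = distance_field(graph, ng)
        sp = nx.multi_source_dijkstra_path_length(graph, ng, weight=None)
        assert field == {k: int(v) for k, v in sp.items()}
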