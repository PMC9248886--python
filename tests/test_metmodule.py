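"""Adduct matching, subnetwork extraction, module scoring and the Gamma null."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from exponet import (
    AdductTable,
    CandidateModule,
    MetabolicNetwork,
    NullModel,
    ScoredModule,
    activity_score,
    detect_modules,
    extract_subnetwork,
    fit_gamma_mle,
    match_features,
    module_pvalues,
    null_distribution,
    simulate_metabolic_study,
    SimulationSpec,
)

POS_H = AdductTable(rows=[("[M+H]+", 1.007276, 1, "+")])


class TestMatchFeatures:
    def test_glucose_proton_adduct_matches(self):
        g = nx.Graph([("glc", "x")])
        net = MetabolicNetwork(graph=g, masses={"glc": 180.0634, "x": 300.0})
        ms = match_features([(181.0707, "+")], net, POS_H, ppm_tol=2.0)
        assert [m.metabolite for m in ms.matches] == ["glc"]
        assert ms.matches[0].ppm_error < 1.0

    def test_empty_feature_list(self):
        net = MetabolicNetwork(graph=nx.Graph([("a", "b")]), masses={"a": 100.0, "b": 200.0})
        assert match_features([], net, POS_H).matches == []

    def test_tolerance_is_a_hard_threshold(self):
        net = MetabolicNetwork(graph=nx.Graph([("glc", "x")]), masses={"glc": 180.0634, "x": 300.0})
        ms = match_features([(181.0707, "+")], net, POS_H, ppm_tol=0.01)
        assert ms.matches == []

    def test_polarity_respected(self):
        net = MetabolicNetwork(graph=nx.Graph([("glc", "x")]), masses={"glc": 180.0634, "x": 300.0})
        ms = match_features([(181.0707, "-")], net, POS_H, ppm_tol=5.0)
        assert ms.matches == []

    def test_empty_adduct_table_errors(self):
        net = MetabolicNetwork(graph=nx.Graph([("a", "b")]), masses={"a": 100.0, "b": 200.0})
        with pytest.raises(ValueError, match="adduct"):
            match_features([(101.0, "+")], net, AdductTable(rows=[]))


class TestExtractSubnetwork:
    def test_hidden_nodes_on_three_step_path(self):
        g = nx.path_graph(["A", "B", "C", "D"])
        net = MetabolicNetwork(graph=g)
        sn = extract_subnetwork(net, {"A", "D"}, max_steps=3)
        assert set(sn.nodes) == {"A", "B", "C", "D"}
        assert sn.nodes["B"]["significant"] is False

    def test_four_step_connection_excluded(self):
        g = nx.path_graph(["A", "B", "C", "D", "E"])
        net = MetabolicNetwork(graph=g)
        sn = extract_subnetwork(net, {"A", "E"}, max_steps=3)
        assert set(sn.nodes) == {"A", "E"}
        assert sn.number_of_edges() == 0

    def test_adjacent_significant_pair(self):
        net = MetabolicNetwork(graph=nx.Graph([("A", "B")]))
        sn = extract_subnetwork(net, {"A", "B"})
        assert set(sn.nodes) == {"A", "B"} and sn.number_of_edges() == 1

    def test_monotone_in_max_steps(self, rng):
        g = nx.gnp_random_graph(30, 0.08, seed=7)
        net = MetabolicNetwork(graph=g)
        sig = set(rng.choice(30, size=6, replace=False).tolist())
        sn2 = extract_subnetwork(net, sig, max_steps=2)
        sn3 = extract_subnetwork(net, sig, max_steps=3)
        assert set(sn2.nodes) <= set(sn3.nodes)

    def test_no_mapped_significant_errors(self):
        net = MetabolicNetwork(graph=nx.Graph([("A", "B")]))
        with pytest.raises(ValueError, match="empty subnetwork"):
            extract_subnetwork(net, {"Z"})


class TestDetectModules:
    def _tagged(self, g):
        nx.set_node_attributes(g, True, "significant")
        return g

    def test_two_cliques_recovered(self, two_cliques_bridge):
        modules = detect_modules(self._tagged(two_cliques_bridge))
        memberships = {frozenset(m.members) for m in modules}
        assert memberships == {frozenset({"a0", "a1", "a2", "a3"}),
                               frozenset({"e0", "e1", "e2", "e3"})}

    def test_tiny_subnetwork_empty(self):
        g = self._tagged(nx.Graph([("A", "B")]))
        assert detect_modules(g) == []

    def test_deterministic(self, two_cliques_bridge):
        g = self._tagged(two_cliques_bridge)
        m1 = detect_modules(g)
        m2 = detect_modules(g)
        assert [m.members for m in m1] == [m.members for m in m2]


def activity_oracle(members, graph, n_input, n_im):
    """Direct pairwise summation over unordered member pairs."""
    m = graph.number_of_edges()
    e_m = graph.subgraph(members).number_of_edges()
    total = 0.0
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            total += (graph.degree(a) / (2 * m)) * (graph.degree(b) / (2 * m))
    q = (n_input / len(members)) * (e_m / m - total)
    return q, q * n_im / len(members)


class TestActivityScore:
    def test_toy_triangle_values(self, toy_metabolic_network):
        mod = CandidateModule(members=["x", "y", "z"], significant_members=["x", "y"])
        q_adj, s = activity_score(mod, toy_metabolic_network, n_input=2)
        assert q_adj == pytest.approx((2 / 3) * (3 / 7 - 16 / 196), abs=1e-12)
        assert q_adj == pytest.approx(0.23129, abs=1e-5)
        assert s == pytest.approx(0.15420, abs=1e-5)

    def test_zero_inputs_zero_score(self, toy_metabolic_network):
        mod = CandidateModule(members=["a", "b", "c"], significant_members=[])
        q_adj, s = activity_score(mod, toy_metabolic_network, n_input=0)
        assert q_adj == 0.0 and s == 0.0

    def test_whole_network_ratio_identity(self, toy_metabolic_network):
        members = sorted(toy_metabolic_network.graph.nodes)
        mod = CandidateModule(members=members, significant_members=members)
        q_adj, s = activity_score(mod, toy_metabolic_network, n_input=len(members))
        assert s == pytest.approx(q_adj, abs=1e-15)

    def test_matches_bruteforce_oracle_on_random_networks(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(0, 2**31)))
            if g.number_of_edges() == 0:
                continue
            net = MetabolicNetwork(graph=g)
            nodes = sorted(g.nodes)
            size = int(rng.integers(2, 8))
            members = sorted(rng.choice(nodes, size=size, replace=False).tolist())
            n_im = int(rng.integers(0, size + 1))
            n_input = n_im + int(rng.integers(0, 4))
            mod = CandidateModule(members=members, significant_members=members[:n_im])
            q_adj, s = activity_score(mod, net, n_input=n_input)
            q_ref, s_ref = activity_oracle(members, g, n_input, n_im)
            assert q_adj == pytest.approx(q_ref, abs=1e-12)
            assert s == pytest.approx(s_ref, abs=1e-12)


class TestGammaNull:
    def test_mle_recovers_known_parameters(self):
        rng = np.random.default_rng(42)
        x = rng.gamma(shape=2.0, scale=3.0, size=10_000)
        shape, scale = fit_gamma_mle(x)
        assert abs(shape - 2.0) / 2.0 < 0.05
        assert abs(scale - 3.0) / 3.0 < 0.05

    def test_degenerate_data_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gamma_mle(np.full(100, 2.5))

    def test_exponential_tail_closed_form(self):
        null = NullModel(s_null=np.array([]), gamma_shape=1.0, gamma_scale=0.7, n_resamples=0)
        theta = 0.7
        mod = CandidateModule(members=["a", "b", "c"], significant_members=["a"])
        sm = ScoredModule(module=mod, q_adj=0.0, s=theta, e_m=0)
        kept = module_pvalues([sm], null, alpha=1.1)
        assert kept[0].p == pytest.approx(math.exp(-1.0), abs=1e-9)

    def test_zero_score_p_is_one_and_large_score_p_small(self):
        null = NullModel(s_null=np.array([]), gamma_shape=2.0, gamma_scale=0.1, n_resamples=0)
        mods = []
        for s in (0.0, 50.0):
            mod = CandidateModule(members=["a", "b", "c"], significant_members=[])
            mods.append(ScoredModule(module=mod, q_adj=0.0, s=s, e_m=0))
        kept = module_pvalues(mods, null, alpha=1.1)
        assert kept[0].p == pytest.approx(1.0)
        assert kept[1].p < 1e-12

    def test_seed_contract(self):
        spec = SimulationSpec(seed=3)
        net, all_f, sig_f, _ = simulate_metabolic_study(spec)
        n1 = null_distribution(all_f, sig_f, net, seed=11)
        n2 = null_distribution(all_f, sig_f, net, seed=11)
        assert np.array_equal(n1.s_null, n2.s_null)
        assert n1.gamma_shape == n2.gamma_shape

    def test_too_few_scores_errors(self):
        spec = SimulationSpec(seed=3)
        net, all_f, sig_f, _ = simulate_metabolic_study(spec)
        with pytest.raises(ValueError, match="n_resamples"):
            null_distribution(all_f, sig_f, net, seed=1, n_resamples=1, min_scores=10_000)
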