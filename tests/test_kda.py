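"""Key driver analysis: neighborhoods, subnetwork, enrichment, recovery."""

from math import comb

import networkx as nx
import numpy as np
import pytest

from sialonet import kda
from sialonet.errors import ValidationError


def oracle_neighborhood(network: nx.DiGraph, gene, h) -> set:
    """Depth-bounded reachability by h rounds of one-step expansion."""
    frontier = {gene}
    reached = set()
    for _ in range(h):
        frontier = {
            child for node in frontier for child in network.successors(node)
        } - reached - {gene}
        reached |= frontier
    return reached


def oracle_hypergeom_tail(n, k_total, draw, overlap) -> float:
    total = comb(n, draw)
    acc = 0
    for k in range(overlap, min(k_total, draw) + 1):
        acc += comb(k_total, k) * comb(n - k_total, draw - k)
    return acc / total


def oracle_kda(network: nx.DiGraph, targets, h_max, alpha):
    """Exhaustive (g, h) enumeration with direct hypergeometric tails."""
    targets = set(targets) & set(network.nodes)
    undirected = network.to_undirected(as_view=True)
    ng = set(targets)
    for t in targets:
        ng |= set(
            nx.single_source_shortest_path_length(undirected, t, cutoff=h_max)
        )
    n_bg = network.number_of_nodes() - 1
    rows = {}
    for g in ng:
        own = targets - {g}
        best_p, best_h = 1.0, 1
        for h in range(1, h_max + 1):
            hln = oracle_neighborhood(network, g, h)
            if not hln:
                p = 1.0
            else:
                p = oracle_hypergeom_tail(n_bg, len(own), len(hln),
                                          len(hln & own))
            if p < best_p - 1e-15:
                best_p, best_h = p, h
        rows[g] = (best_h, best_p, min(1.0, best_p * len(ng)))
    drivers = {g for g, (_, _, pb) in rows.items() if pb < alpha}
    return rows, drivers


def random_dag(n, p, seed) -> nx.DiGraph:
    """Random DAG: edges only forward in a fixed node order."""
    rng = np.random.default_rng(seed)
    net = nx.DiGraph()
    net.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(f"n{i}", f"n{j}")
    return net


class TestNeighborhood:
    def test_chain_hand_enumeration(self):
        net = nx.DiGraph([("a", "b"), ("b", "c")])
        assert kda.h_layer_neighborhood(net, "a", 1) == {"b"}
        assert kda.h_layer_neighborhood(net, "a", 2) == {"b", "c"}

    def test_sink_has_empty_downstream(self):
        net = nx.DiGraph([("a", "b")])
        for h in (1, 2, 5):
            assert kda.h_layer_neighborhood(net, "b", h) == set()

    def test_undirected_mode_sees_parents(self):
        net = nx.DiGraph([("a", "b")])
        assert kda.h_layer_neighborhood(net, "b", 1, "undirected") == {"a"}

    def test_absent_gene_rejected(self):
        with pytest.raises(ValidationError):
            kda.h_layer_neighborhood(nx.DiGraph([("a", "b")]), "zz", 1)

    def test_matches_depth_bounded_oracle_on_random_dags(self):
        for seed in range(30):
            net = random_dag(12, 0.25, seed)
            for g in net:
                for h in (1, 2, 3):
                    assert kda.h_layer_neighborhood(net, g, h) == (
                        oracle_neighborhood(net, g, h)
                    )

    def test_neighborhoods_nested_in_h(self):
        net = random_dag(15, 0.2, seed=99)
        for g in net:
            previous = set()
            for h in range(1, 5):
                current = kda.h_layer_neighborhood(net, g, h)
                assert previous <= current
                previous = current


class TestSubnetwork:
    def test_chain_hand_enumeration(self):
        net = nx.DiGraph([("a", "b"), ("b", "c")])
        assert kda.build_subnetwork_ng(net, {"c"}, 2) == {"a", "b", "c"}

    def test_no_target_in_network_rejected(self):
        net = nx.DiGraph([("a", "b")])
        with pytest.raises(ValidationError):
            kda.build_subnetwork_ng(net, {"zz"}, 2)
        with pytest.raises(ValidationError):
            kda.build_subnetwork_ng(net, {"a"}, 0)

    def test_matches_distance_filter_oracle(self):
        for seed in range(10):
            net = random_dag(14, 0.2, seed)
            undirected = net.to_undirected()
            rng = np.random.default_rng(seed)
            targets = {f"n{i}" for i in rng.choice(14, size=3, replace=False)}
            for h in (1, 2):
                expected = set(targets)
                for t in targets:
                    for node in net:
                        try:
                            d = nx.shortest_path_length(undirected, t, node)
                        except nx.NetworkXNoPath:
                            continue
                        if d <= h:
                            expected.add(node)
                assert kda.build_subnetwork_ng(net, targets, h) == expected


class TestKeyDriverAnalysis:
    def test_star_root_in_background_hand_computed(self):
        net = nx.DiGraph()
        net.add_nodes_from(f"bg{i}" for i in range(44))
        members = [f"m{i}" for i in range(5)]
        net.add_edges_from(("r", m) for m in members)
        drivers = kda.key_driver_analysis(net, set(members), h_max=1,
                                          alpha=0.01)
        assert [d.gene for d in drivers] == ["r"]
        d = drivers[0]
        assert d.scope == "global"
        assert d.p_raw == pytest.approx(1 / comb(49, 5))
        assert d.p_bonferroni == pytest.approx(6 / comb(49, 5))
        assert d.overlap == 5 and d.neighborhood_size == 5

    def test_empty_target_intersection_rejected(self):
        net = nx.DiGraph([("a", "b")])
        with pytest.raises(ValidationError):
            kda.key_driver_analysis(net, {"zz"}, h_max=1)

    def test_bad_alpha_rejected(self):
        net = nx.DiGraph([("a", "b")])
        with pytest.raises(ValidationError):
            kda.key_driver_analysis(net, {"b"}, h_max=1, alpha=0.0)

    def test_candidate_set_matches_exhaustive_oracle(self):
        for seed in range(40):
            net = random_dag(10, 0.3, seed)
            rng = np.random.default_rng(1000 + seed)
            targets = {f"n{i}" for i in rng.choice(10, size=3, replace=False)}
            try:
                ours = kda.key_driver_analysis(net, targets, h_max=2,
                                               alpha=0.05, return_all=True)
            except ValidationError:
                continue
            rows, expected_drivers = oracle_kda(net, targets, 2, 0.05)
            assert {c.gene for c in ours} == set(rows)
            for c in ours:
                h_exp, p_exp, pb_exp = rows[c.gene]
                assert c.p_raw == pytest.approx(p_exp, abs=1e-10)
                assert c.p_bonferroni == pytest.approx(pb_exp, abs=1e-10)
                assert c.h_star == h_exp
            assert {c.gene for c in ours if c.is_key_driver} == expected_drivers

    def test_es_star_nondecreasing_in_h(self):
        net = random_dag(20, 0.15, seed=17)
        targets = {"n15", "n16", "n17"}
        previous = {}
        for h_max in (1, 2, 3, 4):
            try:
                cands = kda.key_driver_analysis(net, targets, h_max=h_max,
                                                return_all=True)
            except ValidationError:
                continue
            es = {c.gene: c.es for c in cands}
            for gene, value in previous.items():
                if gene in es:
                    assert es[gene] >= value - 1e-12
            previous = es

    def test_relabeling_invariance(self):
        net = random_dag(12, 0.3, seed=23)
        targets = {"n8", "n9", "n10"}
        cands = kda.key_driver_analysis(net, targets, h_max=2, return_all=True)
        mapping = {n: f"x{(int(n[1:]) * 5) % 12:02d}" for n in net}
        relabeled = kda.key_driver_analysis(
            nx.relabel_nodes(net, mapping), {mapping[t] for t in targets},
            h_max=2, return_all=True,
        )
        ours = {mapping[c.gene]: (c.h_star, c.p_raw) for c in cands}
        theirs = {c.gene: (c.h_star, c.p_raw) for c in relabeled}
        assert ours == theirs

    def test_planted_driver_recovery(self, small_dataset):
        data = small_dataset
        truth = data.manifest
        module = set(truth.planted_module)
        drivers = kda.key_driver_analysis(
            data.directed_network, module, h_max=3, alpha=0.01
        )
        found = {d.gene for d in drivers}
        assert set(truth.planted_drivers) <= found
        for d in drivers:
            if d.gene in truth.planted_drivers:
                assert d.scope == "global"
        false_positives = found - set(truth.planted_drivers) - module
        assert not false_positives


class TestCorrelation:
    def test_gene_identical_to_score_vector(self):
        import pandas as pd

        samples = [f"s{i}" for i in range(10)]
        scores = pd.Series(np.linspace(0, 1, 10), index=samples)
        expr = pd.DataFrame([scores.to_numpy()], index=["g1"], columns=samples)
        out = kda.correlate_kdg_scores(expr, scores)
        assert out["g1"][0] == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(40):
            samples = [f"s{i}" for i in range(50)]
            scores = pd.Series(rng.normal(size=50), index=samples)
            expr = pd.DataFrame(rng.normal(size=(1, 50)), index=["g"],
                                columns=samples)
            r, _ = kda.correlate_kdg_scores(expr, scores)["g"]
            hits += abs(r) < 0.3
        assert hits >= 36  # ~95% of seeds
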