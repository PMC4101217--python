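"""Cluster property, λ statistic, seed expansion and the full pipeline."""

import math

import pytest

from mcse import (PPINetwork, SeedEdge, build_weighted_network,
                  cluster_property, expand_seed, lambda_value, mcse)
from oracle_util import brute_lambda, random_ppi, simulate_expansion


def _unit_wnet(net):
    """Weighted wrapper where expansion runs on the base (unit) weights."""
    return build_weighted_network(net)


def _seed(u, v, w=1.0, essential=False):
    return SeedEdge(tuple(sorted((u, v))), w, essential)


class TestClusterProperty:
    def test_sums_edge_weights_into_cluster(self):
        net = PPINetwork.from_edges(
            [("v", "h1", 0.5), ("v", "h2", 0.7), ("h1", "h2", 2.0)])
        w = build_weighted_network(net)
        assert cluster_property("v", {"h1", "h2"}, w,
                                use_base=True) == pytest.approx(1.2)

    def test_zero_when_no_neighbor_in_cluster(self, fixtures):
        w = _unit_wnet(fixtures["bridged_triangles"].network)
        assert cluster_property("a", {"d", "e", "f"}, w) == 0.0

    def test_unweighted_counts_edges(self, fixtures):
        w = _unit_wnet(fixtures["K4"].network)
        assert cluster_property("a", {"b"}, w, use_base=True) == 1.0
        assert cluster_property("a", {"b", "c", "d"}, w, use_base=True) == 3.0

    def test_member_vertex_rejected(self, fixtures):
        w = _unit_wnet(fixtures["K3"].network)
        with pytest.raises(ValueError):
            cluster_property("a", {"a", "b"}, w)


class TestLambdaValue:
    def test_isolated_triangle_is_infinite(self, fixtures):
        w = _unit_wnet(fixtures["K3"].network)
        assert lambda_value({"a", "b", "c"}, w) == math.inf

    def test_path_pair(self, fixtures):
        # a-b-c with unit weights, H={a,b}: in-sum 2, out-sum 1
        w = _unit_wnet(fixtures["path3"].network)
        assert lambda_value({"a", "b"}, w, use_base=True) == pytest.approx(2.0)

    def test_triangle_with_one_outgoing_edge(self, fixtures):
        w = _unit_wnet(fixtures["bridged_triangles"].network)
        assert lambda_value({"a", "b", "c"}, w,
                            use_base=True) == pytest.approx(6.0)

    def test_worked_fixture_lambda_tables(self, fixtures):
        for fx in fixtures.values():
            w = _unit_wnet(fx.network)
            for H, expected in fx.lambda_examples.items():
                got = lambda_value(H, w, use_base=True)
                if math.isinf(expected):
                    assert math.isinf(got)
                else:
                    assert got == pytest.approx(expected)

    def test_too_small_cluster_rejected(self, fixtures):
        w = _unit_wnet(fixtures["K3"].network)
        with pytest.raises(ValueError):
            lambda_value({"a"}, w)

    def test_matches_brute_force_on_random_subsets(self, rng):
        for _ in range(20):
            net = random_ppi(rng, int(rng.integers(5, 13)), 0.4)
            w = build_weighted_network(net) if net.n_edges else None
            if w is None:
                continue
            names = sorted(net.vertices)
            for _ in range(10):
                k = int(rng.integers(2, len(names) + 1))
                H = set(rng.choice(names, size=k, replace=False))
                expected = brute_lambda(net, H, w.edge_weight)
                got = lambda_value(H, w)
                if math.isinf(expected):
                    assert math.isinf(got)
                else:
                    assert got == pytest.approx(expected)


class TestExpandSeed:
    def test_isolated_edge_is_immediately_output(self):
        net = PPINetwork.from_edges([("a", "b")])
        w = build_weighted_network(net)
        c = expand_seed(_seed("a", "b"), w, lambda_th=100.0)
        assert c.status == "output"
        assert c.members == frozenset({"a", "b"})
        assert math.isinf(c.final_lambda)

    def test_k4_seed_grows_to_triangle_at_threshold_two(self, fixtures):
        # {a,b}: lambda=2/4 below 2 -> add lexicographically smallest of the
        # tied candidates (c) -> {a,b,c}: in-sum 6, out-sum 3, lambda=2 >= 2
        w = _unit_wnet(fixtures["K4"].network)
        c = expand_seed(_seed("a", "b"), w, lambda_th=2.0)
        assert c.status == "output"
        assert c.members == frozenset({"a", "b", "c"})
        assert c.final_lambda == pytest.approx(2.0)

    def test_fully_covered_seed_is_abandoned(self, fixtures):
        w = _unit_wnet(fixtures["K4"].network)
        c = expand_seed(_seed("a", "b"), w, lambda_th=1.0,
                        covered=set("abcd"))
        assert c.status == "abandoned"
        assert c.final_lambda is None

    def test_half_covered_pair_is_not_abandoned(self, fixtures):
        # 1 of 2 covered is not *more than* half
        net = PPINetwork.from_edges([("a", "b")])
        w = build_weighted_network(net)
        c = expand_seed(_seed("a", "b"), w, lambda_th=1.0, covered={"a"})
        assert c.status == "output"

    def test_nonpositive_threshold_rejected(self, fixtures):
        w = _unit_wnet(fixtures["K3"].network)
        with pytest.raises(ValueError):
            expand_seed(_seed("a", "b"), w, lambda_th=0.0)

    @pytest.mark.parametrize("lambda_th", [0.25, 0.5, 1.0, 2.0, 8.0])
    def test_trace_matches_from_scratch_simulator(self, rng, lambda_th):
        # independent oracle: recompute f and lambda from the definitions
        # at every step, on random graphs of <= 12 vertices
        for _ in range(15):
            net = random_ppi(rng, int(rng.integers(4, 13)), 0.35)
            if net.n_edges == 0:
                continue
            w = build_weighted_network(net)
            names = sorted(net.vertices)
            covered = set(rng.choice(names,
                                     size=int(rng.integers(0, len(names))),
                                     replace=False))
            for e in sorted(w.weights):
                got = expand_seed(_seed(*e), w, lambda_th, covered)
                status, members, lam = simulate_expansion(
                    net, w.edge_weight, e, lambda_th, covered)
                assert got.status == status
                assert got.members == members
                if lam is not None and not math.isinf(lam):
                    assert got.final_lambda == pytest.approx(lam)


class TestMcse:
    def test_two_disjoint_triangles_recovered_at_threshold_two(self, fixtures):
        cs = mcse(fixtures["two_triangles"].network, lambda_th=2.0)
        assert sorted(c.sorted_members() for c in cs) == [
            ["a", "b", "c"], ["d", "e", "f"]]

    def test_low_threshold_emits_tight_pairs(self, fixtures):
        # a 2-vertex seed of an isolated triangle already has lambda = 1
        cs = mcse(fixtures["two_triangles"].network, lambda_th=1.0)
        assert [len(c) for c in cs] == [2, 2]
        assert len(cs.covered_vertices() & {"a", "b", "c"}) == 2

    def test_single_edge_network(self):
        net = PPINetwork.from_edges([("a", "b")])
        cs = mcse(net, lambda_th=0.5)
        assert len(cs) == 1 and cs.complexes[0].members == {"a", "b"}

    def test_output_contracts_on_planted_fixture(self):
        from mcse import generate_planted, lambda_value as lv
        from mcse.weighting import build_weighted_network as bw
        pl = generate_planted(rng_seed=42)
        cs = mcse(pl.network, pl.essentials, lambda_th=1.0)
        w = bw(pl.network)
        emitted = []
        for c in cs:
            assert pl.network.is_connected_subset(c.members)
            assert lv(c.members, w) >= 1.0  # inf compares fine
            prev = set().union(*emitted) if emitted else set()
            assert len(c.members & prev) <= len(c.members) / 2
            emitted.append(set(c.members))

    def test_unweighted_expansion_mode_uses_base_weights(self, rng):
        # seeding identical, expansion differs on a graph where the
        # transform reorders neighbour attractiveness
        for seed in range(30):
            import numpy as np
            net = random_ppi(np.random.default_rng(seed), 12, 0.3)
            if net.n_edges < 3:
                continue
            a = mcse(net, lambda_th=1.0)
            b = mcse(net, lambda_th=1.0, unweighted_expansion=True)
            if a.member_sets() != b.member_sets():
                return  # modes demonstrably diverge
        pytest.fail("unweighted expansion never diverged from weighted")

    def test_determinism_is_byte_identical(self, tmp_path):
        from mcse import generate_planted, write_complex_set
        from mcse.cli import _cset_to_file
        pl = generate_planted(rng_seed=5)
        for i in (1, 2):
            cs = mcse(pl.network, pl.essentials, lambda_th=0.5)
            write_complex_set(_cset_to_file(cs), tmp_path / f"out{i}.txt")
        assert ((tmp_path / "out1.txt").read_bytes()
                == (tmp_path / "out2.txt").read_bytes())

    def test_monotone_nesting_of_greedy_trace(self, rng):
        # replay the simulator step by step: member sets only ever grow
        net = random_ppi(rng, 10, 0.4)
        w = build_weighted_network(net)
        e = sorted(w.weights)[0]
        from mcse.expansion import expand_seed as ex
        small = ex(_seed(*e), w, lambda_th=0.5).members
        big = ex(_seed(*e), w, lambda_th=50.0).members
        assert small <= big
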