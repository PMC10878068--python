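"""Effective information and assortativity against closed forms and oracles."""

import math

import numpy as np
import pytest

from hyperfilter import (
    Hypergraph,
    dynamical_assortativity,
    effective_information,
    pearson_degree_assortativity,
)

from oracles import (
    brute_dynamical_assortativity,
    brute_pearson_assortativity,
    random_hypergraph,
)


class TestEffectiveInformation:
    @pytest.mark.parametrize("n", range(2, 11))
    def test_single_clique_closed_form(self, n):
        # one size-n hyperedge projects to K_n; every row is uniform over the
        # other n-1 nodes, so EI = log2(n) - log2(n-1)
        H = Hypergraph(edges=[set(range(n))])
        ei = effective_information(H)
        assert ei.value == pytest.approx(math.log2(n) - math.log2(n - 1), abs=1e-12)
        assert ei.n_active_nodes == n

    def test_identical_rows_give_zero(self):
        # H(mean of rows) equals mean of H(rows) when all rows coincide;
        # checked directly on the entropy decomposition since a zero-diagonal
        # symmetric projection cannot itself produce identical rows
        from hyperfilter.global_measures import _entropy_bits

        row = np.array([0.5, 0.25, 0.25])
        P = np.tile(row, (4, 1))
        ei = _entropy_bits(P.mean(axis=0)) - np.mean([_entropy_bits(r) for r in P])
        assert ei == pytest.approx(0.0, abs=1e-15)

    def test_row_normalization_makes_multiplicity_irrelevant_for_k2(self):
        # duplicated dyads scale the projection weights but not the
        # l1-normalized transition rows, so EI of K_2 stays exactly 1 bit
        assert effective_information(Hypergraph(edges=[{1, 2}])).value == pytest.approx(1.0, abs=1e-12)
        assert effective_information(Hypergraph(edges=[{1, 2}] * 5)).value == pytest.approx(1.0, abs=1e-12)

    def test_bounds_on_random_instances(self, rng):
        for _ in range(50):
            nodes, edges = random_hypergraph(rng)
            if not any(len(e) >= 2 for e in edges):
                continue
            res = effective_information(Hypergraph(nodes, edges))
            assert -1e-12 <= res.value <= math.log2(res.n_active_nodes) + 1e-12
            norm = effective_information(Hypergraph(nodes, edges), normalized=True)
            assert -1e-12 <= norm.value <= 1 + 1e-12

    def test_undefined_without_pair_edges(self):
        res = effective_information(Hypergraph(edges=[{1}]))
        assert not res.defined

    def test_normalization_divides_by_log_active(self):
        H = Hypergraph(edges=[{1, 2, 3, 4}])
        raw = effective_information(H).value
        norm = effective_information(H, normalized=True).value
        assert norm == pytest.approx(raw / math.log2(4), abs=1e-12)


class TestDynamicalAssortativity:
    def test_regular_hypergraph_is_zero(self):
        # triangle of dyads: every node has degree 2
        H = Hypergraph(edges=[{1, 2}, {2, 3}, {1, 3}])
        assert dynamical_assortativity(H).value == pytest.approx(0.0, abs=1e-14)

    def test_path_value_by_hand(self, path3):
        # degrees 1, 2, 1: <k>=4/3, <k^2>=2, <k k1>_E=2 -> rho = -1/9
        assert dynamical_assortativity(path3).value == pytest.approx(-1 / 9, abs=1e-14)

    def test_lower_bound(self, rng):
        for _ in range(50):
            nodes, edges = random_hypergraph(rng)
            if not any(len(e) >= 2 for e in edges):
                continue
            assert dynamical_assortativity(Hypergraph(nodes, edges)).value >= -1 - 1e-12

    @pytest.mark.parametrize("weighting", ["per_edge", "pooled"])
    def test_matches_brute_force(self, rng, weighting):
        checked = 0
        while checked < 100:
            nodes, edges = random_hypergraph(rng)
            if not any(len(e) >= 2 for e in edges):
                continue
            got = dynamical_assortativity(
                Hypergraph(nodes, edges), pair_weighting=weighting
            ).value
            want = brute_dynamical_assortativity(nodes, edges, weighting)
            assert got == pytest.approx(want, abs=1e-10)
            checked += 1

    def test_undefined_without_pair_edges(self):
        assert not dynamical_assortativity(Hypergraph(edges=[{1}])).defined


class TestPearsonAssortativity:
    def test_regular_degrees_undefined(self):
        H = Hypergraph(edges=[{1, 2}, {3, 4}])
        for rule in ("top_bottom", "top_2", "uniform"):
            assert not pearson_degree_assortativity(H, rule=rule).defined

    def test_hub_and_leaves_is_disassortative(self):
        # every edge pairs the hub (high degree) with fresh leaves
        edges = [{0, i, i + 1} for i in range(1, 10, 2)]
        H = Hypergraph(edges=edges)
        for rule in ("top_bottom", "uniform"):
            r = pearson_degree_assortativity(H, rule=rule).value
            assert r < 0

    @pytest.mark.parametrize("rule", ["top_bottom", "top_2", "uniform"])
    def test_matches_brute_force(self, rng, rule):
        checked = 0
        while checked < 100:
            nodes, edges = random_hypergraph(rng)
            got = pearson_degree_assortativity(Hypergraph(nodes, edges), rule=rule)
            want = brute_pearson_assortativity(nodes, edges, rule)
            if math.isnan(want):
                assert not got.defined
            else:
                assert got.value == pytest.approx(want, abs=1e-10)
                assert -1 - 1e-12 <= got.value <= 1 + 1e-12
            checked += 1

    def test_symmetrization_order_invariance(self, rng):
        # relabeling nodes (which permutes within-edge order) leaves r unchanged
        nodes, edges = random_hypergraph(rng, allow_dupes=False)
        H = Hypergraph(nodes, edges)
        perm = {v: -v - 1 for v in nodes}
        H2 = Hypergraph([perm[v] for v in nodes], [{perm[v] for v in e} for e in edges])
        for rule in ("top_bottom", "top_2", "uniform"):
            a = pearson_degree_assortativity(H, rule=rule).value
            b = pearson_degree_assortativity(H2, rule=rule).value
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b, abs=1e-12)

    def test_excess_degree_mode_shifts_both_coordinates(self, rng):
        nodes, edges = random_hypergraph(rng, allow_dupes=False)
        H = Hypergraph(nodes, edges)
        full = pearson_degree_assortativity(H, rule="uniform", degree_mode="full")
        exc = pearson_degree_assortativity(H, rule="uniform", degree_mode="excess")
        # a constant shift of both coordinates cannot change a correlation
        if full.defined and exc.defined:
            assert exc.value == pytest.approx(full.value, abs=1e-12)
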