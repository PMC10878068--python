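"""Synthetic generators: determinism, exact spectra, planted recovery."""

import math
from collections import Counter

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from hyperfilter import (
    GeneratorSpec,
    Hypergraph,
    dynamical_assortativity,
    planted_partition_hypergraph,
    preprocess,
    random_uniform_hypergraph,
    size_filter,
    size_stratified_hypergraph,
    spectral_communities,
)
from hyperfilter.generators import generate_from_spec


def _ari(labeling, truth):
    common = [v for v in truth if labeling[v] != -1]
    return adjusted_rand_score([truth[v] for v in common], [labeling[v] for v in common])


class TestRandomUniform:
    def test_exhaustive_draw_is_complete_graph(self):
        H = random_uniform_hypergraph(4, 6, 2, seed=0)
        assert set(H.edges) == {frozenset(p) for p in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]}

    def test_deterministic_given_seed(self):
        a = random_uniform_hypergraph(12, 10, 3, seed=9)
        b = random_uniform_hypergraph(12, 10, 3, seed=9)
        assert a.edges == b.edges

    def test_edges_distinct_and_exact_count(self):
        H = random_uniform_hypergraph(10, 30, 3, seed=2)
        assert H.num_edges == 30
        assert len(set(H.edges)) == 30
        assert all(len(e) == 3 for e in H.edges)

    def test_capacity_errors(self):
        with pytest.raises(ValueError, match="exceeds C"):
            random_uniform_hypergraph(4, 7, 2, seed=0)
        with pytest.raises(ValueError, match="exceeds n"):
            random_uniform_hypergraph(3, 1, 4, seed=0)

    def test_mean_dynamical_assortativity_vanishes_with_size(self):
        # the null model has no planted degree-degree structure, but rho
        # carries a finite-size negative bias (sharing an edge nudges both
        # endpoint degrees up together); the bias must shrink roughly like
        # 1/n and be small in absolute terms at moderate size
        means = []
        for n, m in [(20, 15), (40, 60), (80, 240)]:
            vals = [
                dynamical_assortativity(random_uniform_hypergraph(n, m, 3, seed=s)).value
                for s in range(60)
            ]
            means.append(abs(float(np.mean(vals))))
        assert means == sorted(means, reverse=True)
        assert means[-1] < 0.01


class TestPlantedPartition:
    def test_full_bias_keeps_edges_within_communities(self):
        H, labels = planted_partition_hypergraph(
            n=30, edge_sizes={2: 20, 3: 15}, c=2, p_in=1.0, seed=4
        )
        for e in H.edges:
            assert len({labels[v] for v in e}) == 1

    def test_recovery_at_full_bias(self):
        H, labels = planted_partition_hypergraph(
            n=40, edge_sizes={2: 60, 3: 40}, c=2, p_in=1.0, seed=11
        )
        lab = spectral_communities(H, c=2, seed=0)
        assert _ari(lab, labels) == 1.0

    def test_zero_bias_matches_uniform_sampling(self):
        # p_in = 0 never draws from a community pool: distribution over edges
        # is uniform per size, so the same rng seed path yields valid draws
        H, _ = planted_partition_hypergraph(
            n=15, edge_sizes={3: 25}, c=3, p_in=0.0, seed=7
        )
        assert Counter(len(e) for e in H.edges) == {3: 25}
        union = set().union(*H.edges)
        assert len(union) > 5  # edges spread over the whole node set

    def test_single_community_labels_all_equal(self):
        _, labels = planted_partition_hypergraph(
            n=10, edge_sizes={2: 5}, c=1, p_in=1.0, seed=0
        )
        assert set(labels.values()) == {0}

    def test_community_too_small_raises(self):
        with pytest.raises(ValueError, match="large enough"):
            planted_partition_hypergraph(
                n=6, edge_sizes={5: 3}, c=2, p_in=1.0, seed=0
            )

    def test_passes_preprocess_unchanged(self):
        H, _ = planted_partition_hypergraph(
            n=30, edge_sizes={2: 20, 4: 10}, c=2, p_in=0.8, seed=3
        )
        assert preprocess(H).edges == H.edges


class TestSizeStratified:
    def test_defaults_shape(self):
        H, la, lb = size_stratified_hypergraph(seed=0)
        assert H.num_nodes == 64
        assert Counter(H.edge_sizes()) == {2: 80, 3: 60, 5: 40, 6: 30}
        assert la != lb  # two genuinely different partitions

    def test_strata_respect_their_partition(self):
        H, la, lb = size_stratified_hypergraph(seed=1)
        for e in H.edges:
            truth = la if len(e) <= 3 else lb
            assert len({truth[v] for v in e}) == 1

    def test_equal_partitions_reduce_to_planted_partition(self):
        lab = [0] * 10 + [1] * 10
        H, la, lb = size_stratified_hypergraph(
            n=20,
            sizes_small={2: 15},
            sizes_large={4: 8},
            labels_small=lab,
            labels_large=lab,
            seed=5,
        )
        assert la == lb
        for e in H.edges:
            assert len({la[v] for v in e}) == 1

    def test_absent_size_filtering_is_empty(self):
        H, _, _ = size_stratified_hypergraph(seed=0)
        assert size_filter(H, "eq", 4).num_edges == 0

    def test_deterministic_given_seed(self):
        a, _, _ = size_stratified_hypergraph(seed=8)
        b, _, _ = size_stratified_hypergraph(seed=8)
        assert a.edges == b.edges

    def test_filtered_clustering_recovers_both_partitions(self):
        # the headline property: filtering by size exposes two community
        # structures that whole-hypergraph clustering cannot match at once
        successes = 0
        n_runs = 20
        for seed in range(n_runs):
            H, la, lb = size_stratified_hypergraph(seed=seed)
            leq = spectral_communities(size_filter(H, "leq", 3), c=2, seed=0)
            geq = spectral_communities(size_filter(H, "geq", 4), c=2, seed=0)
            full = spectral_communities(H, c=2, seed=0)
            ari_leq_a = _ari(leq, la)
            ari_geq_b = _ari(geq, lb)
            ari_full_a = _ari(full, la)
            ari_full_b = _ari(full, lb)
            if (ari_leq_a > ari_full_a) or (ari_geq_b > ari_full_b):
                successes += 1
        assert successes >= 0.9 * n_runs

    def test_overlapping_size_strata_rejected(self):
        with pytest.raises(ValueError, match="below"):
            size_stratified_hypergraph(
                n=20, sizes_small={3: 5}, sizes_large={3: 5}, seed=0
            )


class TestGeneratorSpec:
    def test_config_round_trip(self, tmp_path):
        spec = GeneratorSpec(
            n=32, edge_sizes={2: 10, 5: 4}, c=2, p_in=0.9, seed=3,
            stratified=True, k0=3, c_large=2,
        )
        p = tmp_path / "spec.cfg"
        spec.to_file(str(p))
        assert GeneratorSpec.from_file(str(p)) == spec

    def test_dispatch_stratified(self):
        spec = GeneratorSpec(
            n=32, edge_sizes={2: 30, 5: 12}, c=2, p_in=1.0, seed=1,
            stratified=True, k0=3, c_large=2,
        )
        H, la, lb = generate_from_spec(spec)
        assert H.num_nodes == 32
        assert la != lb

    def test_validation(self):
        with pytest.raises(ValueError, match="p_in"):
            GeneratorSpec(n=5, edge_sizes={2: 1}, p_in=1.5)
        with pytest.raises(ValueError, match="k0"):
            GeneratorSpec(n=5, edge_sizes={2: 1, 3: 1}, stratified=True)
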