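"""Seed-connectivity hypergeometric testing and friend calling."""

import numpy as np
import pandas as pd
import pytest

from coexnet.errors import ConfigurationError, EmptyResultError
from coexnet.friends import (
    SeedSet,
    call_friends,
    read_friend_table,
    read_seed_list,
    seed_neighbor_counts,
    seed_self_connectivity,
    test_all_genes as score_all_genes,
    write_friend_table,
)
from coexnet.network import build_network
from coexnet.simulate import SimulationConfig, generate_paired_dataset

from conftest import exact_upper_tail


def by_gene(results):
    return {r.gene: r for r in results}


class TestNeighborCounts:
    def test_star_hub_counts_seed_neighbours(self, network_factory):
        net = network_factory(edges=[("hub", x) for x in ["s1", "s2", "s3", "x1", "x2"]])
        seed = SeedSet(frozenset({"s1", "s2", "s3"}))
        counts = {g: (k, n) for g, k, n in seed_neighbor_counts(net, seed)}
        assert counts["hub"] == (3, 5)
        assert counts["s1"] == (0, 1)  # its only neighbour is the non-seed hub

    def test_isolated_gene_has_zero_counts(self, network_factory):
        net = network_factory(edges=[("s1", "a")], nodes=["lonely"])
        counts = {g: (k, n) for g, k, n in seed_neighbor_counts(net, SeedSet(frozenset({"s1"})))}
        assert counts["lonely"] == (0, 0)

    def test_seed_gene_is_not_its_own_neighbour(self, network_factory):
        net = network_factory(edges=[("s1", "s2"), ("s1", "s3")], nodes=["b1", "b2"])
        seed = SeedSet(frozenset({"s1", "s2", "s3"}))
        counts = {g: (k, n) for g, k, n in seed_neighbor_counts(net, seed)}
        assert counts["s1"] == (2, 2)

    def test_seed_absent_from_universe_is_an_error(self, network_factory):
        net = network_factory(edges=[("a", "b")])
        with pytest.raises(EmptyResultError, match="MISSING1"):
            seed_neighbor_counts(net, SeedSet(frozenset({"MISSING1"})))


class TestTestAllGenes:
    def test_zero_degree_gene_has_p_one(self, network_factory):
        net = network_factory(edges=[("s1", "s2")], nodes=["iso"])
        res = by_gene(score_all_genes(net, SeedSet(frozenset({"s1", "s2"}))))
        assert res["iso"].p_value == 1.0

    def test_complete_graph_forced_draw(self, network_factory):
        nodes = [f"g{i}" for i in range(10)]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        net = network_factory(edges=edges)
        seed = SeedSet(frozenset(nodes[:4]))
        res = by_gene(score_all_genes(net, seed))
        r = res["g9"]
        assert (r.k, r.n, r.K_eff, r.N_eff) == (4, 9, 4, 9)
        assert r.p_value == 1.0  # all seeds necessarily drawn when n = N_eff

    def test_seed_gene_tested_against_remaining_seeds(self, network_factory):
        net = network_factory(
            edges=[("s1", "s2"), ("s1", "s3"), ("s1", "x")], nodes=["b1"]
        )
        seed = SeedSet(frozenset({"s1", "s2", "s3"}))
        res = by_gene(score_all_genes(net, seed))
        r = res["s1"]
        assert (r.k, r.n, r.K_eff, r.N_eff) == (2, 3, 2, 4)
        expected = float(exact_upper_tail(2, 3, 2, 4))
        assert r.p_value == pytest.approx(expected, rel=1e-12)

    def test_results_sorted_by_p_then_gene(self, network_factory):
        net = network_factory(
            edges=[("s1", "a"), ("s1", "s2"), ("s2", "s1")], nodes=["z1", "z2"]
        )
        res = score_all_genes(net, SeedSet(frozenset({"s1", "s2"})))
        keys = [(r.log10_p, r.gene) for r in res]
        assert keys == sorted(keys)

    def test_p_values_invariant_under_common_sample_permutation(self):
        rng = np.random.default_rng(21)
        cfg = SimulationConfig(n_genes=60, seed_size=10, n_true_friends=5,
                               n_samples_normal=30, rng_seed=4)
        normal, _, truth = generate_paired_dataset(cfg)
        seed = SeedSet(truth.seed_genes)
        perm = rng.permutation(normal.shape[1])
        shuffled = normal.iloc[:, perm]
        res_a = score_all_genes(build_network(normal), seed)
        res_b = score_all_genes(build_network(shuffled), seed)
        assert [(r.gene, r.p_value) for r in res_a] == [(r.gene, r.p_value) for r in res_b]


class TestCallFriends:
    def _results(self, network_factory):
        net = network_factory(edges=[("s1", "s2"), ("s1", "x")], nodes=["b"])
        return net, SeedSet(frozenset({"s1", "s2"}))

    def test_all_p_one_gives_empty_set(self, network_factory):
        net = network_factory(nodes=["s1", "a", "b"])
        res = score_all_genes(net, SeedSet(frozenset({"s1"})))
        assert call_friends(res, alpha=1e-8).members == frozenset()

    def test_cutoff_is_strict(self, network_factory):
        net, seed = self._results(network_factory)
        res = score_all_genes(net, seed)
        # alpha=1 includes exactly the genes with p strictly below 1
        members = call_friends(res, alpha=1.0).members
        assert members == {r.gene for r in res if r.p_value < 1.0}

    def test_seed_genes_excluded_by_default(self, network_factory):
        net, seed = self._results(network_factory)
        res = score_all_genes(net, seed)
        with_seed = call_friends(res, seed=seed, alpha=1.0, exclude_seed=False).members
        without = call_friends(res, seed=seed, alpha=1.0).members
        assert without == with_seed - seed.symbols

    def test_alpha_validation(self, network_factory):
        net, seed = self._results(network_factory)
        res = score_all_genes(net, seed)
        for alpha in (0.0, -1.0, 1.5):
            with pytest.raises(ConfigurationError):
                call_friends(res, alpha=alpha)

    def test_planted_friends_recovered_on_one_replicate(self):
        cfg = SimulationConfig(rng_seed=11)  # study-scale defaults
        normal, _, truth = generate_paired_dataset(cfg)
        net = build_network(normal)
        seed = SeedSet(truth.seed_genes)
        friends = call_friends(score_all_genes(net, seed), seed=seed).members
        recall = len(friends & truth.true_friends) / len(truth.true_friends)
        assert recall >= 0.9
        # a handful of background genes chance-correlate with the latent
        # factor and genuinely attach to the module; the rate stays low
        fp_rate = len(friends & truth.background_genes) / len(truth.background_genes)
        assert fp_rate <= 0.01


class TestSeedSelfConnectivity:
    def test_fully_connected_seed_in_sparse_background(self, network_factory):
        seeds = [f"s{i}" for i in range(6)]
        edges = [(a, b) for i, a in enumerate(seeds) for b in seeds[i + 1 :]]
        net = network_factory(edges=edges, nodes=[f"b{i}" for i in range(200)])
        seed = SeedSet(frozenset(seeds))
        res = score_all_genes(net, seed)
        connected = seed_self_connectivity(res, seed, alpha=1e-8)
        assert connected == frozenset(seeds)
        # oracle: each seed has k = n = 5 of K_eff = 5 among N_eff = 205
        expected = float(exact_upper_tail(5, 5, 5, 205))
        assert by_gene(res)["s0"].p_value == pytest.approx(expected, rel=1e-10)
        assert expected < 1e-8

    def test_degree_zero_seed_never_returned(self, network_factory):
        net = network_factory(edges=[("s1", "s2")], nodes=["s3"])
        seed = SeedSet(frozenset({"s1", "s2", "s3"}))
        res = score_all_genes(net, seed)
        assert "s3" not in seed_self_connectivity(res, seed, alpha=1.0)


class TestNullCalibration:
    def test_no_friend_calls_under_the_null(self):
        # with all loadings zero the network edges are pure threshold noise;
        # no gene should ever reach the 1e-8 friend cutoff
        for rep in range(20):
            cfg = SimulationConfig(
                n_genes=300, seed_size=30, n_true_friends=0,
                loading_seed=0.0, loading_friend=0.0,
                n_samples_treated=5, rng_seed=1000 + rep,
            )
            normal, _, truth = generate_paired_dataset(cfg)
            seed = SeedSet(truth.seed_genes)
            res = score_all_genes(build_network(normal), seed)
            assert min(r.p_value for r in res) >= 1e-8


class TestFriendTableIO:
    def test_round_trip_and_sorting(self, tmp_path, network_factory):
        net = network_factory(
            edges=[("s1", "s2"), ("s1", "a"), ("s2", "a"), ("b", "c")],
            nodes=["iso"],
        )
        seed = SeedSet(frozenset({"s1", "s2"}))
        res = score_all_genes(net, seed)
        write_friend_table(res, tmp_path / "friends.tsv")
        back = read_friend_table(tmp_path / "friends.tsv")
        assert [(r.gene, r.k, r.n, r.K_eff, r.N_eff) for r in back] == [
            (r.gene, r.k, r.n, r.K_eff, r.N_eff) for r in res
        ]
        for orig, rt in zip(res, back):
            assert rt.p_value == pytest.approx(orig.p_value, rel=1e-6)
        ps = [r.p_value for r in back]
        assert ps == sorted(ps)

    def test_empty_results_write_header_only(self, tmp_path):
        write_friend_table([], tmp_path / "friends.tsv")
        lines = (tmp_path / "friends.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("gene\t")

    def test_q_value_column_present(self, tmp_path, network_factory):
        net = network_factory(edges=[("s1", "a")])
        res = score_all_genes(net, SeedSet(frozenset({"s1"})))
        write_friend_table(res, tmp_path / "friends.tsv")
        df = pd.read_csv(tmp_path / "friends.tsv", sep="\t")
        assert "q_value" in df.columns
        assert (df.q_value >= df.p_value - 1e-15).all()


class TestSeedListIO:
    def test_comments_and_blanks_ignored(self, tmp_path):
        p = tmp_path / "seed.txt"
        p.write_text("# complex I\nNDUFB5\nNDUFA7  # subunit\n\nUQCRC2\n")
        seed = read_seed_list(p)
        assert seed.symbols == {"NDUFB5", "NDUFA7", "UQCRC2"}

    def test_empty_list_is_an_error(self, tmp_path):
        p = tmp_path / "seed.txt"
        p.write_text("# nothing\n")
        with pytest.raises(EmptyResultError):
            read_seed_list(p)
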