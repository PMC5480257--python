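import networkx as nx
import numpy as np
import pytest

from biogeodiv.hapnet import (Haplotype, HaplotypeAlignment,
                              HaplotypeNetwork, build_network,
                              collapse_haplotypes, concat_loci,
                              network_stats, outgroup_connection,
                              parsimony_limit, resolve_ambiguities,
                              step_distance)
from biogeodiv.synthdata import SimConfig, simulate_haplotypes


def aln(seqs, ids=None, meta=None):
    ids = ids or [f"s{i}" for i in range(1, len(seqs) + 1)]
    return HaplotypeAlignment(ids, seqs, meta)


class TestCollapse:
    def test_simple_classes(self):
        haps = collapse_haplotypes(aln(["AAA", "AAA", "AAT"]))
        assert [(h.id, h.frequency) for h in haps] == [(1, 2), (2, 1)]

    def test_gap_is_missing(self):
        haps = collapse_haplotypes(aln(["AAA", "A-A"]))
        assert len(haps) == 1
        assert haps[0].sequence == "AAA"   # consensus fills the gap

    def test_fully_missing_site_stays_n(self):
        haps = collapse_haplotypes(aln(["A-A", "A-A"]))
        assert haps[0].sequence == "ANA"

    def test_earliest_class_wins_and_conflicts_logged(self):
        # third sample is compatible with both earlier classes
        haps, n = collapse_haplotypes(aln(["AAT", "AAG", "AA-"]),
                                      return_conflicts=True)
        assert n == 1
        assert haps[0].frequency == 2     # joined the earliest class

    def test_sample_counts_conserved_per_region(self):
        cfg = SimConfig(seed=31)
        alignment, _ = simulate_haplotypes(cfg)
        haps = collapse_haplotypes(alignment)
        by_region = {}
        for h in haps:
            for a, c in h.areas.items():
                by_region[a] = by_region.get(a, 0) + c
        truth = alignment.metadata.groupby("area")["sample_id"].count()
        assert by_region == truth.to_dict()

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            collapse_haplotypes(HaplotypeAlignment([], []))


class TestStepDistance:
    def test_symmetric_and_zero_iff_compatible(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT-N"))
        for _ in range(50):
            a = "".join(rng.choice(bases, size=30))
            b = "".join(rng.choice(bases, size=30))
            assert step_distance(a, b) == step_distance(b, a)
            arr_a, arr_b = np.array(list(a)), np.array(list(b))
            both = ~np.isin(arr_a, list("-N")) & ~np.isin(arr_b,
                                                          list("-N"))
            compatible = bool(np.all(arr_a[both] == arr_b[both]))
            assert (step_distance(a, b) == 0) == compatible

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            step_distance("AAA", "AA")


class TestParsimonyLimit:
    def test_fixed_override(self):
        assert parsimony_limit(100, fixed=12) == 12

    def test_at_least_one_for_any_length(self):
        assert parsimony_limit(1) >= 1
        assert parsimony_limit(10) >= 1

    def test_non_decreasing_in_length_and_matches_direct_product(self):
        prev = 0
        for m in range(500, 5001, 250):
            j = parsimony_limit(m)
            assert j >= prev
            prev = j
            # direct re-computation of the no-homoplasy product
            def p(j, m=m):
                out = 1.0
                for i in range(1, j + 1):
                    out *= 1.0 - 0.75 * (i - 1) / m
                return out
            assert p(j) > 0.95
            assert p(j + 1) <= 0.95


class TestBuildNetwork:
    def test_chain_path_graph(self):
        haps = collapse_haplotypes(aln(["AAAA", "AAAT", "AATT"]))
        net = build_network(haps, limit=12)
        assert sorted(net.graph.edges) == [("H1", "H2"), ("H2", "H3")]
        assert not net.loops

    def test_limit_splits_components(self):
        far = "T" * 20 + "A" * 10
        near = "A" * 30
        haps = collapse_haplotypes(aln([near, near[:-1] + "T", far]))
        net = build_network(haps, limit=12)
        comps = list(nx.connected_components(net.graph))
        assert len(comps) == 2

    def test_intermediates_for_multi_step_links(self):
        haps = collapse_haplotypes(aln(["AAAA", "AATT"]))
        net = build_network(haps, limit=12)
        inter = [n for n in net.graph.nodes if n.startswith("I")]
        assert len(inter) == 1
        assert net.graph.degree[inter[0]] == 2

    def test_star_truth(self):
        cfg = SimConfig(seed=18, gap_fraction=0.0)
        alignment, truth = simulate_haplotypes(
            cfg, structure=[("star", 8, "E")])
        haps = collapse_haplotypes(alignment)
        assert len(haps) == 9
        net = build_network(haps, limit=parsimony_limit(alignment.n_sites))
        degrees = sorted(d for _, d in net.graph.degree)
        assert degrees == [1] * 8 + [8]


class TestResolve:
    @staticmethod
    def four_cycle(freqs, areas=None):
        g = nx.Graph()
        areas = areas or [frozenset()] * 4
        for i, (f, a) in enumerate(zip(freqs, areas), start=1):
            g.add_node(f"H{i}", frequency=f, areas=a)
        for u, v in [(1, 2), (2, 3), (3, 4), (4, 1)]:
            g.add_edge(f"H{u}", f"H{v}", dashed=False)
        haps = {i: Haplotype(i, "A" * 4, ["x"] * f)
                for i, f in enumerate(freqs, start=1)}
        return HaplotypeNetwork(graph=g, haplotypes=haps, limit=10)

    def test_four_cycle_keeps_high_frequency_edges(self):
        net = self.four_cycle([10, 1, 1, 1])
        resolved = resolve_ambiguities(net)
        assert not resolved.loops
        removed = resolved.resolution_log[-1]["removed"]
        # both edges touching the frequency-10 node survive; the edge
        # removed joins two frequency-1 nodes
        assert "H1" not in removed
        assert resolved.graph.has_edge("H1", "H2")
        assert resolved.graph.has_edge("H1", "H4")
        # exhaustive check: no alternative removal keeps a lower-ranked
        # edge set (all four options tried)
        for alt in [("H1", "H2"), ("H1", "H4")]:
            assert max(net.graph.nodes[n]["frequency"] for n in alt) == 10

    def test_geography_breaks_topology_ties(self):
        E, D = frozenset("E"), frozenset("D")
        net = self.four_cycle([1, 1, 1, 1], areas=[E, E, D, E])
        resolved = resolve_ambiguities(net)
        removed = resolved.resolution_log[-1]["removed"]
        # the only cross-region edges are H2-H3 and H3-H4; one of them
        # goes
        assert "H3" in removed

    def test_loop_free_identity(self):
        haps = collapse_haplotypes(aln(["AAAA", "AAAT", "AATT"]))
        net = build_network(haps, limit=12)
        resolved = resolve_ambiguities(net)
        assert sorted(resolved.graph.edges) == sorted(net.graph.edges)

    def test_resolution_never_disconnects(self):
        rng = np.random.default_rng(19)
        for rep in range(10):
            cfg = SimConfig(seed=800 + rep, gap_fraction=0.05)
            alignment, _ = simulate_haplotypes(cfg)
            haps = collapse_haplotypes(alignment)
            net = build_network(haps,
                                parsimony_limit(alignment.n_sites))
            n_before = nx.number_connected_components(net.graph)
            resolved = resolve_ambiguities(net)
            assert not resolved.loops
            assert nx.number_connected_components(resolved.graph) == \
                n_before


class TestStats:
    def test_path_classification(self):
        haps = collapse_haplotypes(aln(["AAAA", "AAAT", "AATT"]))
        net = resolve_ambiguities(build_network(haps, limit=12))
        stats = network_stats(net)
        assert stats.interior_unambiguous == [2]
        assert stats.tips == [1, 3]

    def test_class_means_from_given_memberships(self):
        # 6 interior haplotypes carrying 29 samples, 14 tips carrying 23:
        # a path of interiors with pendant tips
        g = nx.Graph()
        interior_freqs = [5, 5, 5, 5, 5, 4]          # 29 samples
        tip_freqs = [2] * 9 + [1] * 5                # 23 samples
        haps = {}
        for i, f in enumerate(interior_freqs, start=1):
            g.add_node(f"H{i}", frequency=f, areas=frozenset())
            haps[i] = Haplotype(i, "A", [f"s{i}_{j}" for j in range(f)])
            if i > 1:
                g.add_edge(f"H{i-1}", f"H{i}", dashed=False)
        for k, f in enumerate(tip_freqs):
            hid = 7 + k
            anchor = 1 + k % 6
            g.add_node(f"H{hid}", frequency=f, areas=frozenset())
            haps[hid] = Haplotype(hid, "A",
                                  [f"t{hid}_{j}" for j in range(f)])
            g.add_edge(f"H{anchor}", f"H{hid}", dashed=False)
        net = HaplotypeNetwork(graph=g, haplotypes=haps, limit=10)
        stats = network_stats(net)
        assert len(stats.interior_unambiguous) == 6
        assert len(stats.tips) == 14
        assert round(stats.mean_samples["tip"], 2) == 1.64
        assert round(stats.mean_samples["interior_unambiguous"], 1) == 4.8
        assert stats.interior_vs_tip_test.df == 1
        # both singleton statistics are emitted
        assert 0 <= stats.singleton_fraction["tip"] <= 1
        assert stats.singleton_ratio["tip"] >= 0

    def test_unresolved_loops_rejected(self):
        net = TestResolve.four_cycle([1, 1, 1, 1])
        with pytest.raises(ValueError, match="resolve_ambiguities"):
            network_stats(net)


class TestOutgroup:
    def test_identical_zero_intermediates(self):
        haps = collapse_haplotypes(aln(["AAAA", "AATT"]))
        conn = outgroup_connection(haps, "AAAA")
        assert conn.haplotype_ids == [1]
        assert conn.intermediates == 0

    def test_steps_minus_one(self):
        haps = collapse_haplotypes(aln(["A" * 30]))
        out = "T" * 17 + "A" * 13
        conn = outgroup_connection(haps, out)
        assert conn.steps == 17
        assert conn.intermediates == 16

    def test_ties_all_reported(self):
        haps = collapse_haplotypes(aln(["AAAA", "TTTT"]))
        conn = outgroup_connection(haps, "AATT")
        assert conn.haplotype_ids == [1, 2]

    def test_length_mismatch_rejected(self):
        haps = collapse_haplotypes(aln(["AAAA"]))
        with pytest.raises(ValueError, match="length"):
            outgroup_connection(haps, "AAAAA")


class TestConcat:
    def test_requires_all_loci(self):
        a1 = aln(["AA", "CC", "GG"], ids=["x", "y", "z"])
        a2 = aln(["TT", "AA"], ids=["x", "y"])
        cat = concat_loci([a1, a2])
        assert cat.sample_ids == ["x", "y"]
        assert cat.sequences == ["AATT", "CCAA"]
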