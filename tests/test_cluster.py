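"""Graph construction, community partition, superclusters, contigs."""

import math

import networkx as nx
import numpy as np
import pytest

from repeatome.cluster import (
    Cluster,
    ClusteringParams,
    SimilarityParams,
    apply_size_threshold,
    assemble_contigs,
    brute_force_graph,
    build_similarity_graph,
    build_superclusters,
    cluster_truth_majority,
    partition_clusters,
    quantify_clusters,
)
from repeatome.core import ReadPair, ReadSet
from repeatome.simulate import (
    GenomeComponent,
    GenomeSpec,
    ReadSimParams,
    RepeatFamily,
    build_parental_genome,
    random_consensus,
    simulate_reads,
)

Q = chr(35 + 33)


def pair(pid, s1, s2, **kw):
    return ReadPair(pid, s1, Q * len(s1), s2, Q * len(s2), **kw)


def edge_set(g):
    return {frozenset(e) for e in g.edges()}


class TestGraph:
    def test_production_equals_oracle_on_simulated_reads(self, small_parent_genome):
        rs = simulate_reads(small_parent_genome, ReadSimParams(coverage=0.08), 31)
        p = SimilarityParams()
        prod = build_similarity_graph(rs, p)
        oracle = brute_force_graph(rs, p)
        assert edge_set(prod) == edge_set(oracle)

    def test_tandem_array_reads_form_connected_graph(self, rng):
        """Error-free reads from a 1 kb tandem array are all similar."""
        unit = random_consensus(100, rng)
        array = unit * 10
        reads = [array[i * 45 : i * 45 + 150] for i in range(10)]
        rs = ReadSet([pair(f"r{i}", reads[i], reads[(i + 1) % 10]) for i in range(5)])
        g = build_similarity_graph(rs, SimilarityParams())
        assert nx.is_connected(g)
        assert edge_set(g) == edge_set(brute_force_graph(rs, SimilarityParams()))

    def test_two_families_no_cross_edges(self, rng, two_family_spec):
        g = build_parental_genome(two_family_spec, 41)
        rs = simulate_reads(g, ReadSimParams(coverage=0.15), 42)
        graph = build_similarity_graph(rs, SimilarityParams())
        truth = {}
        for p in rs:
            truth[f"{p.id}/1"] = p.truth
            truth[f"{p.id}/2"] = p.truth
        cross = [
            (u, v)
            for u, v in graph.edges()
            if truth[u] != truth[v]
            and "background" not in (truth[u], truth[v])
        ]
        assert cross == []

    def test_duplicated_read_is_adjacent(self, rng):
        s = random_consensus(150, rng)
        rs = ReadSet(
            [pair("a", s, random_consensus(150, rng)), pair("b", s, random_consensus(150, rng))]
        )
        g = build_similarity_graph(rs, SimilarityParams())
        assert g.has_edge("a/1", "b/1")


class TestPartition:
    def test_components_become_clusters(self):
        g = nx.Graph()
        g.add_edges_from([("a/1", "b/1"), ("b/1", "c/1"), ("x/1", "y/1")])
        g.add_node("lone/1")
        clusters, singlets = partition_clusters(g, ClusteringParams())
        assert [c.size for c in clusters] == [3, 2]
        assert clusters[0].id == 1 and clusters[1].id == 2
        assert singlets == ["lone/1"]

    def test_relabeling_reads_leaves_partition_invariant(self, small_parent_genome):
        rs = simulate_reads(small_parent_genome, ReadSimParams(coverage=0.06), 51)
        renamed = ReadSet(
            [
                ReadPair(f"zz{i:04d}", p.seq1, p.qual1, p.seq2, p.qual2)
                for i, p in enumerate(reversed(rs.pairs))
            ]
        )
        p = SimilarityParams()
        c1, s1 = partition_clusters(build_similarity_graph(rs, p), ClusteringParams())
        c2, s2 = partition_clusters(build_similarity_graph(renamed, p), ClusteringParams())
        assert sorted(c.size for c in c1) == sorted(c.size for c in c2)
        assert len(s1) == len(s2)

    def test_cluster_purity_on_two_family_genome(self, rng, two_family_spec):
        g = build_parental_genome(two_family_spec, 61)
        rs = simulate_reads(g, ReadSimParams(coverage=1.0), 62)
        graph = build_similarity_graph(rs, SimilarityParams())
        clusters, _ = partition_clusters(graph, ClusteringParams())
        truth = {}
        for p in rs:
            truth[f"{p.id}/1"] = p.truth
            truth[f"{p.id}/2"] = p.truth
        big = [c for c in clusters if c.size >= 50]
        assert len(big) >= 2
        for c in big:
            maj = cluster_truth_majority(c, truth)
            purity = sum(1 for r in c.read_ids if truth[r] == maj) / c.size
            assert purity >= 0.90


class TestThreshold:
    def test_threshold_arithmetic_at_printed_input_size(self):
        """0.01 % of a 4,349,101-read input means >= 435 reads."""
        total = 4_349_101
        cut = ClusteringParams().size_threshold * total
        assert math.ceil(cut) == 435
        c_above = Cluster(1, frozenset(f"r{i}/1" for i in range(435)), 435, 0)
        c_below = Cluster(2, frozenset(f"s{i}/1" for i in range(434)), 434, 0)
        above, below = apply_size_threshold([c_above, c_below], total, ClusteringParams())
        assert [c.id for c in above] == [1]
        assert [c.id for c in below] == [2]

    def test_zero_threshold_keeps_all(self):
        c = Cluster(1, frozenset(["a/1", "a/2"]), 2, 0)
        above, below = apply_size_threshold(
            [c], 10**6, ClusteringParams(size_threshold=0.0)
        )
        assert below == []


def _two_linked_clusters(shared, unpaired_x, unpaired_y):
    """Build clusters X, Y with given split-pair structure.

    X holds ``shared`` reads whose mates are in Y, ``unpaired_x - shared``
    reads with mates outside both, plus internal whole pairs; same for Y.
    """
    x_reads, y_reads = set(), set()
    for i in range(shared):
        x_reads.add(f"sh{i}/1")
        y_reads.add(f"sh{i}/2")
    for i in range(unpaired_x - shared):
        x_reads.add(f"ux{i}/1")  # mate /2 not in any cluster
    for i in range(unpaired_y - shared):
        y_reads.add(f"uy{i}/1")
    for i in range(5):  # internal pairs, not unpaired
        x_reads |= {f"ix{i}/1", f"ix{i}/2"}
        y_reads |= {f"iy{i}/1", f"iy{i}/2"}
    cx = Cluster(1, frozenset(x_reads), len(x_reads), 0)
    cy = Cluster(2, frozenset(y_reads), len(y_reads), 0)
    return [cx, cy]


class TestSuperclusters:
    def test_no_shared_pairs_no_merge(self):
        clusters = _two_linked_clusters(0, 10, 10)
        scs = build_superclusters(clusters, ClusteringParams())
        assert sorted(len(s.member_cluster_ids) for s in scs) == [1, 1]

    def test_ratio_above_threshold_merges(self):
        # shared 7, unpaired 40 + 20: 7/60 = 0.1167 > 0.1
        clusters = _two_linked_clusters(7, 40, 20)
        scs = build_superclusters(clusters, ClusteringParams())
        assert [sorted(s.member_cluster_ids) for s in scs] == [[1, 2]]

    def test_ratio_exactly_threshold_does_not_merge(self):
        # shared 6, unpaired 40 + 20: 6/60 = 0.10, strict inequality
        clusters = _two_linked_clusters(6, 40, 20)
        scs = build_superclusters(clusters, ClusteringParams())
        assert sorted(len(s.member_cluster_ids) for s in scs) == [1, 1]

    def test_closure_is_partition(self):
        clusters = _two_linked_clusters(7, 40, 20)
        clusters.append(Cluster(3, frozenset({"zz0/1", "zz1/1"}), 2, 0))
        scs = build_superclusters(clusters, ClusteringParams())
        members = sorted(m for s in scs for m in s.member_cluster_ids)
        assert members == [1, 2, 3]


class TestQuantify:
    def test_single_sample_proportions(self):
        c = Cluster(1, frozenset({"s:a/1", "s:a/2", "s:b/1"}), 3, 0)
        table = quantify_clusters([c], {f"s:{r}/{m}": "s" for r in "ab" for m in (1, 2)}, {"s": 10})
        assert table.loc[0, "count"] == 3
        assert table.loc[0, "proportion"] == pytest.approx(0.3)

    def test_unknown_sample_rejected(self):
        c = Cluster(1, frozenset({"q:a/1"}), 1, 0)
        with pytest.raises(KeyError):
            quantify_clusters([c], {"q:a/1": "q"}, {"s": 10})

    def test_conservation_with_singlets(self, small_parent_genome):
        rs = simulate_reads(small_parent_genome, ReadSimParams(coverage=0.1), 71)
        rs = rs.with_sample("A")
        graph = build_similarity_graph(rs, SimilarityParams())
        clusters, singlets = partition_clusters(graph, ClusteringParams())
        som = {}
        for p in rs:
            som[f"{p.id}/1"] = "A"
            som[f"{p.id}/2"] = "A"
        table = quantify_clusters(clusters, som, {"A": rs.n_reads})
        total = table["proportion"].sum() + len(singlets) / rs.n_reads
        assert total == pytest.approx(1.0)


class TestContigs:
    def test_error_free_tiling_reconstructs_template(self, rng):
        template = random_consensus(600, rng)
        reads = {
            f"r{i:02d}/1": template[s : s + 150]
            for i, s in enumerate(range(0, 451, 50))
        }
        c = Cluster(1, frozenset(reads), len(reads), 0)
        contigs = assemble_contigs(c, reads)
        assert contigs == [template]

    def test_two_separate_groups_give_two_contigs(self, rng):
        t1 = random_consensus(300, rng)
        t2 = random_consensus(300, rng)
        reads = {}
        for i, s in enumerate(range(0, 151, 75)):
            reads[f"a{i}/1"] = t1[s : s + 150]
            reads[f"b{i}/1"] = t2[s : s + 150]
        c = Cluster(1, frozenset(reads), len(reads), 0)
        contigs = assemble_contigs(c, reads)
        assert len(contigs) == 2
        assert {len(x) for x in contigs} == {300}

    def test_identical_reads_give_the_read(self, rng):
        s = random_consensus(150, rng)
        reads = {f"r{i}/1": s for i in range(4)}
        c = Cluster(1, frozenset(reads), 4, 0)
        assert assemble_contigs(c, reads) == [s]
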