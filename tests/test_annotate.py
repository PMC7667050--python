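"""Annotation, supercluster propagation, tandem detection, screening."""

import numpy as np
import pytest

from repeatome._align import revcomp
from repeatome.annotate import (
    AnnotationParams,
    annotate_cluster,
    classify_category,
    detect_tandem_monomer,
    domain_db_from_families,
    propagate_supercluster_annotation,
    screen_reads_by_reference,
)
from repeatome.cluster import Cluster, ClusteringParams, SimilarityParams, Supercluster
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


def _cluster_with_hits(rng, n_reads, n_hitting, domain_seq):
    """A cluster of random reads of which ``n_hitting`` contain the domain."""
    reads = {}
    for i in range(n_reads):
        if i < n_hitting:
            s = int(rng.integers(0, len(domain_seq) - 150))
            seq = domain_seq[s : s + 150]
        else:
            seq = random_consensus(150, rng)
        reads[f"r{i:03d}/1"] = seq
    cluster = Cluster(1, frozenset(reads), n_reads, 0)
    return cluster, reads


class TestAnnotateCluster:
    DB = None

    def _db(self, rng):
        return {
            "tekay.dom0": (random_consensus(800, rng), "Ty3/Gypsy:chromovirus/Tekay"),
        }

    def test_six_percent_hits_annotates(self, rng):
        db = self._db(rng)
        cluster, reads = _cluster_with_hits(rng, 200, 12, db["tekay.dom0"][0])
        res = annotate_cluster(cluster, reads, db)
        assert res.lineage == "Ty3/Gypsy:chromovirus/Tekay"
        assert res.hit_fraction == pytest.approx(0.06)

    def test_under_five_percent_unclassified(self, rng):
        db = self._db(rng)
        cluster, reads = _cluster_with_hits(rng, 200, 9, db["tekay.dom0"][0])
        res = annotate_cluster(cluster, reads, db)
        assert res.lineage == "unclassified"

    def test_zero_hits_unclassified(self, rng):
        db = self._db(rng)
        cluster, reads = _cluster_with_hits(rng, 50, 0, db["tekay.dom0"][0])
        assert annotate_cluster(cluster, reads, db).lineage == "unclassified"

    def test_conflicting_lineages_flagged(self, rng):
        dom1 = random_consensus(600, rng)
        dom2 = random_consensus(600, rng)
        db = {"a": (dom1, "Ty1/Copia:SIRE"), "b": (dom2, "Ty3/Gypsy:chromovirus/Tekay")}
        reads = {}
        for i in range(10):
            reads[f"a{i}/1"] = dom1[i : i + 150]
        for i in range(20):
            reads[f"b{i}/1"] = dom2[i : i + 150]
        for i in range(70):
            reads[f"c{i}/1"] = random_consensus(150, rng)
        cluster = Cluster(1, frozenset(reads), 100, 0)
        res = annotate_cluster(cluster, reads, db)
        assert res.conflict
        assert res.lineage == "Ty3/Gypsy:chromovirus/Tekay"

    def test_empty_db_rejected(self, rng):
        cluster, reads = _cluster_with_hits(rng, 10, 0, random_consensus(300, rng))
        with pytest.raises(ValueError):
            annotate_cluster(cluster, reads, {})


class TestSuperclusterPropagation:
    def test_unannotated_member_inherits_majority(self):
        clusters = [
            Cluster(1, frozenset({"a/1"}), 300, 0),
            Cluster(2, frozenset({"b/1"}), 100, 0),
        ]
        sc = [Supercluster(1, frozenset({1, 2}))]
        eff = propagate_supercluster_annotation(
            sc, clusters, {1: "Ty3/Gypsy:chromovirus/Tekay", 2: "unclassified"}
        )
        assert eff[2] == "Ty3/Gypsy:chromovirus/Tekay"

    def test_existing_annotation_never_overwritten(self):
        clusters = [
            Cluster(1, frozenset({"a/1"}), 300, 0),
            Cluster(2, frozenset({"b/1"}), 100, 0),
        ]
        sc = [Supercluster(1, frozenset({1, 2}))]
        eff = propagate_supercluster_annotation(
            sc, clusters, {1: "Ty3/Gypsy:chromovirus/Tekay", 2: "Ty1/Copia:SIRE"}
        )
        assert eff[2] == "Ty1/Copia:SIRE"

    def test_tie_warns_and_stays_unclassified(self):
        clusters = [
            Cluster(1, frozenset({"a/1"}), 100, 0),
            Cluster(2, frozenset({"b/1"}), 100, 0),
            Cluster(3, frozenset({"c/1"}), 50, 0),
        ]
        sc = [Supercluster(1, frozenset({1, 2, 3}))]
        with pytest.warns(UserWarning, match="tied"):
            eff = propagate_supercluster_annotation(
                sc, clusters, {1: "Ty1/Copia:SIRE", 2: "Ty3/Gypsy:chromovirus/Tekay"}
            )
        assert eff.get(3, "unclassified") == "unclassified"

    def test_supercluster_level_proportion_at_least_cluster_level(self):
        """A family split over linked clusters gains mass at supercluster level."""
        sizes = {1: 200, 2: 120, 3: 80}
        clusters = [Cluster(i, frozenset({f"x{i}/1"}), s, 0) for i, s in sizes.items()]
        sc = [Supercluster(1, frozenset({1, 2, 3}))]
        anns = {1: "Ty1/Copia:SIRE"}
        eff = propagate_supercluster_annotation(sc, clusters, anns)
        cl_mass = sum(sizes[c] for c, a in anns.items() if a == "Ty1/Copia:SIRE")
        sc_mass = sum(sizes[c] for c, a in eff.items() if a == "Ty1/Copia:SIRE")
        assert sc_mass >= cl_mass


class TestTandemDetection:
    def test_exact_three_monomer_array(self, rng):
        unit = random_consensus(126, rng)
        rep = detect_tandem_monomer(unit * 3)
        assert rep is not None
        assert rep.monomer_length == 126
        assert rep.copies_in_contig == pytest.approx(3.0)
        assert rep.monomer_consensus == unit

    def test_mutated_46bp_array(self, rng):
        unit = random_consensus(46, rng)
        arr = list((unit * 5)[:207])
        for i in rng.choice(len(arr), size=10, replace=False):
            arr[int(i)] = "ACGT"[("ACGT".index(arr[int(i)]) + 1) % 4]
        rep = detect_tandem_monomer("".join(arr))
        assert rep is not None and rep.monomer_length == 46

    def test_random_sequences_give_none(self):
        """No spurious monomer calls on random sequence (false-positive check)."""
        for seed in range(40):
            r = np.random.default_rng(seed)
            assert detect_tandem_monomer(random_consensus(300, r)) is None

    def test_smallest_qualifying_lag_reported(self, rng):
        """A dimer-periodic contig reports the monomer, not the dimer."""
        unit = random_consensus(60, rng)
        rep = detect_tandem_monomer(unit * 6)
        assert rep.monomer_length == 60

    def test_short_contig_returns_none(self, rng):
        assert detect_tandem_monomer(random_consensus(40, rng)) is None


class TestScreening:
    def test_absent_reference_scores_zero(self, rng, small_reads):
        refs = {"absent": random_consensus(2000, rng)}
        out = screen_reads_by_reference(small_reads, refs)
        assert out["absent"] == 0.0

    def test_planted_satellite_proportion_recovered(self, rng):
        """Satellite at 0.5 % of bases: screen within 3 binomial SE."""
        sat_unit = random_consensus(150, rng)
        sat = RepeatFamily("sat", "satellite:sat", sat_unit * 4, monomer_length=150)
        filler = RepeatFamily("fill", "Ty1/Copia:SIRE", random_consensus(5000, rng))
        spec = GenomeSpec(
            "g",
            (GenomeComponent(sat, 2, 0.0), GenomeComponent(filler, 16, 0.0)),
            background_length=158_800,
        )
        g = build_parental_genome(spec, 81)
        truth = g.truth_proportions()["sat"]
        assert truth == pytest.approx(0.005, rel=0.1)
        rs = simulate_reads(g, ReadSimParams(coverage=0.3, error_rate=0.0), 82)
        out = screen_reads_by_reference(rs, {"sat": sat.consensus})
        p_hat = out["sat"] / 100
        se = (truth * (1 - truth) / len(rs)) ** 0.5
        assert abs(p_hat - truth) <= 3 * se + 1e-9

    def test_subthreshold_repeat_found_by_screen_not_clustering(self, rng):
        """A very rare satellite yields screen hits but no above-threshold
        cluster: the screen-positive / clustering-negative discordance."""
        from repeatome.cluster import (
            apply_size_threshold,
            build_similarity_graph,
            partition_clusters,
        )

        sat_unit = random_consensus(100, rng)
        sat = RepeatFamily("sat", "satellite:sat", sat_unit * 3, monomer_length=100)
        filler = RepeatFamily("fill", "Ty1/Copia:SIRE", random_consensus(6000, rng))
        spec = GenomeSpec(
            "g",
            (GenomeComponent(sat, 1, 0.0), GenomeComponent(filler, 10, 0.0)),
            background_length=139_700,
        )
        g = build_parental_genome(spec, 91)
        rs = simulate_reads(g, ReadSimParams(coverage=0.3, error_rate=0.0), 92)
        out = screen_reads_by_reference(rs, {"sat": sat.consensus})
        assert out["sat"] > 0
        graph = build_similarity_graph(rs, SimilarityParams())
        clusters, _ = partition_clusters(graph, ClusteringParams())
        # a 0.15 % satellite cannot form a sizable cluster at this depth
        truth = {}
        for p in rs:
            truth[f"{p.id}/1"] = p.truth
            truth[f"{p.id}/2"] = p.truth
        sat_clusters = [
            c
            for c in clusters
            if c.size >= 10
            and sum(1 for r in c.read_ids if truth[r] == "sat") > c.size / 2
        ]
        assert sat_clusters == []


class TestCategories:
    @pytest.mark.parametrize(
        "lineage,category",
        [
            ("Ty1/Copia:SIRE", "Ty1/Copia"),
            ("chromovirus/Tekay", "Ty3/Gypsy"),
            ("Ty3/Gypsy:non-chromovirus/OTA/Athila", "Ty3/Gypsy"),
            ("pararetrovirus", "pararetrovirus"),
            ("DNA-transposon:EnSpm_CACTA", "DNA transposons"),
            ("Helitron", "Helitron"),
            ("satellite:CL229", "satellite DNA"),
            ("45S-rDNA", "45S rDNA"),
            ("5S-rDNA", "5S rDNA"),
        ],
    )
    def test_known_lineages(self, lineage, category):
        assert classify_category(lineage) == category

    def test_unknown_label_warns_unclassified(self):
        with pytest.warns(UserWarning):
            assert classify_category("FooBar") == "unclassified"

    def test_domain_db_built_from_families(self, rng):
        fam = RepeatFamily(
            "f",
            "Ty1/Copia:SIRE",
            random_consensus(2000, rng),
            domain_segments=((500, 1200, "Ty1/Copia:SIRE"),),
        )
        db = domain_db_from_families([fam])
        assert db["f.dom0"][1] == "Ty1/Copia:SIRE"
        assert len(db["f.dom0"][0]) == 700
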