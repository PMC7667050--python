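"""End-to-end orchestration: simulate -> prep -> cluster -> compare.

These helpers wire the library modules together for the three analysis
modes (comparative, individual, bias) and are what the CLI, the manifest
runner and the acceptance measurements call.  Sample datasets are always
subsampled to equal per-1C coverage before joint clustering, mirroring
the comparative design the statistics assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import compare as comp
from .cluster import (
    Cluster,
    ClusteringParams,
    SimilarityParams,
    apply_size_threshold,
    build_similarity_graph,
    build_superclusters,
    cluster_truth_majority,
    partition_clusters,
    quantify_clusters,
)
from .core import ReadSet
from .readprep import SampleMeta, quality_filter, subsample_to_coverage
from .simulate import (
    Genome,
    HybridSpec,
    ReadSimParams,
    build_hybrid_genome,
    build_parental_genome,
    comparative_parent_specs,
    reads_for_c1_coverage,
    simulate_reads,
)

MAX_SAMPLES_PER_RUN = 3


def derive_seed(seed: int, k: int) -> int:
    """Deterministic per-stage sub-seed, kept below 2**31."""
    return int((seed * 1_000_003 + k * 7919 + 17) % 2_147_483_647)


@dataclass
class RunResult:
    """Joint clustering of up to three coverage-equalized samples."""

    samples: list[str]
    totals: dict[str, int]  # reads input per sample (incl. singlets)
    clusters_above: list[Cluster]
    clusters_below: list[Cluster]
    singlets: list[str]
    abundance: pd.DataFrame  # above-threshold clusters
    truth_of_cluster: dict[int, str] = field(default_factory=dict)
    sample_of_read: dict[str, str] = field(default_factory=dict)
    seq_of_read: dict[str, str] = field(default_factory=dict)

    def counts(self, sample: str) -> pd.Series:
        sub = self.abundance[self.abundance["sample"] == sample]
        return pd.Series(
            sub["count"].to_numpy(float), index=sub["cluster_id"].to_numpy(int)
        ).sort_index()

    def proportions(self, sample: str) -> pd.Series:
        return self.counts(sample) / self.totals[sample]

    def below_fraction(self, sample: str) -> float:
        n = sum(
            1
            for c in self.clusters_below
            for r in c.read_ids
            if self.sample_of_read[r] == sample
        )
        return n / self.totals[sample]

    def singlet_fraction(self, sample: str) -> float:
        n = sum(1 for r in self.singlets if self.sample_of_read[r] == sample)
        return n / self.totals[sample]


def sample_meta_for_genome(
    genome: Genome, role: str, dosage: tuple[int, int] | None = None
) -> SampleMeta:
    ploidy = 3 if (dosage and sum(dosage) == 3) else 2
    return SampleMeta(
        id=genome.label,
        species=genome.label,
        ploidy=ploidy,
        size_2C_pg=genome.size_2C_pg(),
        role=role,
        dosage=dosage,
    )


def comparative_run(
    datasets: dict[str, ReadSet],
    metas: dict[str, SampleMeta],
    target_coverage: float,
    seed: int,
    sim: SimilarityParams | None = None,
    clus: ClusteringParams | None = None,
    max_samples: int = MAX_SAMPLES_PER_RUN,
) -> RunResult:
    """Equalize coverage, pool, joint-cluster and quantify."""
    if len(datasets) > max_samples:
        raise ValueError(f"at most {max_samples} samples per comparative run")
    sim = sim or SimilarityParams()
    clus = clus or ClusteringParams(seed=seed)
    pooled = []
    totals: dict[str, int] = {}
    for k, (sid, rs) in enumerate(sorted(datasets.items())):
        sub = subsample_to_coverage(
            rs, metas[sid], target_coverage, seed=derive_seed(seed, k)
        )
        sub = sub.with_sample(sid).with_id_prefix(f"{sid}:")
        totals[sid] = sub.n_reads
        pooled.extend(sub.pairs)
    joint = ReadSet(pooled)
    graph = build_similarity_graph(joint, sim)
    clusters, singlets = partition_clusters(graph, clus)
    above, below = apply_size_threshold(clusters, joint.n_reads, clus)
    sample_of_read: dict[str, str] = {}
    seq_of_read: dict[str, str] = {}
    truth_of_read: dict[str, str] = {}
    for p in joint:
        for mate, seq in ((1, p.seq1), (2, p.seq2)):
            rid = f"{p.id}/{mate}"
            sample_of_read[rid] = p.sample
            seq_of_read[rid] = seq
            if p.truth is not None:
                truth_of_read[rid] = p.truth
    abundance = quantify_clusters(above, sample_of_read, totals)
    truth_of_cluster = (
        {c.id: cluster_truth_majority(c, truth_of_read) for c in clusters}
        if truth_of_read
        else {}
    )
    return RunResult(
        samples=sorted(datasets),
        totals=totals,
        clusters_above=above,
        clusters_below=below,
        singlets=singlets,
        abundance=abundance,
        truth_of_cluster=truth_of_cluster,
        sample_of_read=sample_of_read,
        seq_of_read=seq_of_read,
    )


def hybrid_deviation(
    run: RunResult,
    parent_a: str,
    parent_b: str,
    hybrid: str,
    dosage: tuple[int, int],
) -> tuple[list[comp.DeviationRecord], float, list[int]]:
    """Deviation scores of one hybrid against its dosage expectation."""
    expected = comp.expected_hybrid_counts(
        run.counts(parent_a), run.counts(parent_b), dosage
    )
    annotations = {
        cid: fam
        for cid, fam in run.truth_of_cluster.items()
    }
    return comp.deviation_scores(run.counts(hybrid), expected, annotations)


def family_mean_scores(
    records: list[comp.DeviationRecord],
    min_expected: float = 4.0,
) -> dict[str, float]:
    """Mean deviation score per (truth-annotated) family.

    Clusters with tiny expectations are excluded: a ratio of counts of
    order one is pure noise.  Background clusters are not a family.
    """
    by_fam: dict[str, list[float]] = {}
    for r in records:
        if r.expected < min_expected:
            continue
        fam = r.annotation
        if fam in ("unclassified", "background"):
            continue
        by_fam.setdefault(fam, []).append(r.score)
    return {f: float(np.mean(v)) for f, v in by_fam.items()}


# ------------------------------------------------------------- simulated runs


def simulate_comparative_system(
    dosage: tuple[int, int],
    seed: int,
    genome_length: int = 5_000_000,
    bursts: tuple[tuple[str, float], ...] = (),
    library_coverage: float = 0.12,
    sim_params: ReadSimParams | None = None,
) -> tuple[dict[str, ReadSet], dict[str, SampleMeta]]:
    """Simulate two parents and one hybrid, as sequenced libraries.

    Libraries are drawn at ``library_coverage`` so that the comparative
    run exercises the subsampling step when cutting down to the analysis
    coverage.  The hybrid role/ploidy follows the dosage (1,1 -> diploid
    synthetic F1; otherwise triploid natural hybrid).
    """
    spec_a, spec_b = comparative_parent_specs(genome_length=genome_length)
    hyb_spec = HybridSpec("hybrid", spec_a, spec_b, dosage, bursts=bursts)
    mix = 13 * (4 * dosage[0] + dosage[1])  # decorrelate runs across dosages
    g_a = build_parental_genome(spec_a, derive_seed(seed, 101 + mix))
    g_b = build_parental_genome(spec_b, derive_seed(seed, 102 + mix))
    g_h = build_hybrid_genome(hyb_spec, derive_seed(seed, 103 + mix))
    base = sim_params or ReadSimParams()
    datasets: dict[str, ReadSet] = {}
    metas: dict[str, SampleMeta] = {}
    for k, (g, role, dos) in enumerate(
        (
            (g_a, "parent", None),
            (g_b, "parent", None),
            (
                g_h,
                "synthetic_hybrid" if sum(dosage) == 2 else "natural_hybrid",
                dosage,
            ),
        )
    ):
        p = ReadSimParams(
            read_length=base.read_length,
            insert_mean=base.insert_mean,
            insert_sd=base.insert_sd,
            error_rate=base.error_rate,
            coverage=reads_for_c1_coverage(g, library_coverage),
        )
        rs = simulate_reads(g, p, derive_seed(seed, 110 + k), sample=g.label)
        rs = quality_filter(rs)
        datasets[g.label] = rs
        metas[g.label] = sample_meta_for_genome(g, role, dos)
    return datasets, metas


def burst_recovery_run(
    seed: int,
    burst_family: str = "sire_like",
    burst_factor: float = 1.5,
    dosage: tuple[int, int] = (2, 1),
    target_coverage: float = 0.066,
    genome_length: int = 5_000_000,
) -> dict[str, float]:
    """One burst-recovery replicate: per-family mean deviation scores."""
    datasets, metas = simulate_comparative_system(
        dosage, seed, genome_length, bursts=((burst_family, burst_factor),)
    )
    run = comparative_run(datasets, metas, target_coverage, seed)
    records, _, _ = hybrid_deviation(run, "parentA", "parentB", "hybrid", dosage)
    return family_mean_scores(records)


def informative_clusters(
    run: RunResult, parent_a: str, parent_b: str, min_parental_reads: int = 8
) -> pd.Index:
    """Clusters with enough parental evidence to inform dosage statistics.

    The customary 0.01 %-of-input cluster threshold corresponds to
    hundreds of reads at production depth but to less than one read at
    desk scale, where it would admit 2-3 read background clusters whose
    count ratios are pure noise; an absolute floor on the summed parental
    reads is the scale-invariant equivalent.
    """
    s = run.counts(parent_a) + run.counts(parent_b)
    return s[s >= min_parental_reads].index


def null_calibration_run(
    seed: int,
    dosage: tuple[int, int],
    target_coverage: float = 0.066,
    genome_length: int = 5_000_000,
    min_parental_reads: int = 8,
) -> dict[str, object]:
    """Burst-free replicate: cumulative score and intermediacy direction."""
    datasets, metas = simulate_comparative_system(dosage, seed, genome_length)
    run = comparative_run(datasets, metas, target_coverage, seed)
    records, cumulative, _ = hybrid_deviation(
        run, "parentA", "parentB", "hybrid", dosage
    )
    scored = [r for r in records if r.expected >= 4.0]
    mean_score = float(np.mean([r.score for r in scored])) if scored else 0.0
    weighted = (
        sum(r.observed for r in scored) / sum(r.expected for r in scored) - 1.0
        if scored
        else 0.0
    )
    keep = informative_clusters(run, "parentA", "parentB", min_parental_reads)
    inter = comp.intermediacy_analysis(
        run.counts("parentA").reindex(keep, fill_value=0.0),
        run.counts("parentB").reindex(keep, fill_value=0.0),
        run.counts("hybrid").reindex(keep, fill_value=0.0),
        hybrid_ploidy=3 if sum(dosage) == 3 else 2,
    )
    return {
        "family_scores": family_mean_scores(records),
        "mean_score": mean_score,
        "weighted_score": float(weighted),
        "n_scored": len(scored),
        "intermediacy": inter,
    }


def bias_tier_pair(
    seed: int,
    tier: str,
    subsample_pairs: int = 1000,
    genome_length: int = 2_000_000,
    library_coverage: float = 0.18,
    min_cluster_reads: int = 8,
) -> tuple[pd.Series, pd.Series]:
    """Two coverage-matched datasets for one bias tier, jointly clustered.

    Tiers: ``intra_library`` (two subsamples of one parent-A library),
    ``inter_library`` (two independent libraries of parent A),
    ``inter_specific`` (one parent-A vs one parent-B library subsample).
    Returns the two per-cluster proportion profiles.
    """
    spec_a, spec_b = comparative_parent_specs(genome_length=genome_length)
    g_a = build_parental_genome(spec_a, derive_seed(seed, 201))
    cov = library_coverage

    def library(g, k):
        p = ReadSimParams(coverage=reads_for_c1_coverage(g, cov))
        return simulate_reads(g, p, derive_seed(seed, 210 + k), sample=g.label)

    def subsample(rs, k):
        if subsample_pairs > len(rs):
            raise ValueError(
                f"subsample of {subsample_pairs} pairs exceeds library size "
                f"{len(rs)}; raise library_coverage or genome_length"
            )
        idx = np.sort(
            np.random.default_rng(derive_seed(seed, 240 + k)).choice(
                len(rs), size=subsample_pairs, replace=False
            )
        )
        return ReadSet(rs[int(i)] for i in idx)

    if tier == "intra_library":
        lib = library(g_a, 0)
        s1, s2 = subsample(lib, 0), subsample(lib, 1)
    elif tier == "inter_library":
        s1, s2 = subsample(library(g_a, 0), 0), subsample(library(g_a, 1), 1)
    elif tier == "inter_specific":
        g_b = build_parental_genome(spec_b, derive_seed(seed, 202))
        s1, s2 = subsample(library(g_a, 0), 0), subsample(library(g_b, 2), 1)
    else:
        raise ValueError(f"unknown tier {tier!r}")
    pooled = []
    totals = {}
    for name, s in (("s1", s1), ("s2", s2)):
        s = s.with_sample(name).with_id_prefix(f"{name}:")
        totals[name] = s.n_reads
        pooled.extend(s.pairs)
    joint = ReadSet(pooled)
    graph = build_similarity_graph(joint, SimilarityParams())
    clusters, singlets = partition_clusters(graph, ClusteringParams(seed=seed))
    above, _ = apply_size_threshold(clusters, joint.n_reads, ClusteringParams())
    sample_of_read = {}
    for p in joint:
        sample_of_read[f"{p.id}/1"] = p.sample
        sample_of_read[f"{p.id}/2"] = p.sample
    ab = quantify_clusters(above, sample_of_read, totals)
    p1 = pd.Series(
        ab[ab["sample"] == "s1"]["proportion"].to_numpy(),
        index=ab[ab["sample"] == "s1"]["cluster_id"].to_numpy(int),
    )
    p2 = pd.Series(
        ab[ab["sample"] == "s2"]["proportion"].to_numpy(),
        index=ab[ab["sample"] == "s2"]["cluster_id"].to_numpy(int),
    )
    counts = pd.Series(
        ab[ab["sample"] == "s1"]["count"].to_numpy(float),
        index=ab[ab["sample"] == "s1"]["cluster_id"].to_numpy(int),
    ) + pd.Series(
        ab[ab["sample"] == "s2"]["count"].to_numpy(float),
        index=ab[ab["sample"] == "s2"]["cluster_id"].to_numpy(int),
    )
    # evidence floor: the desk-scale analogue of the 0.01 %-of-input rule,
    # which at production depth means hundreds of reads per cluster
    keep = counts[counts >= min_cluster_reads].index
    return p1.reindex(keep, fill_value=0.0), p2.reindex(keep, fill_value=0.0)


# --------------------------------------------------------------- manifest modes


def comparative_mode(manifest: dict, seed: int) -> dict:
    if "dosage" not in manifest:
        raise ValueError("comparative manifest: missing required key 'dosage'")
    dosage = tuple(int(d) for d in manifest["dosage"])
    target = float(manifest.get("target_coverage", 0.066))
    glen = int(manifest.get("genome_length", 1_000_000))
    bursts = tuple(
        (b["family"], float(b["factor"])) for b in manifest.get("bursts", [])
    )
    lib_cov = float(manifest.get("library_coverage", 2 * target))
    datasets, metas = simulate_comparative_system(
        dosage, seed, glen, bursts=bursts, library_coverage=lib_cov
    )
    run = comparative_run(datasets, metas, target, seed)
    records, cumulative, novel = hybrid_deviation(
        run, "parentA", "parentB", "hybrid", dosage
    )
    table = pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "observed": r.observed,
                "expected": r.expected,
                "score": r.score,
                "family": r.annotation,
            }
            for r in records
        ]
    )
    keep = informative_clusters(run, "parentA", "parentB")
    inter = comp.intermediacy_analysis(
        run.counts("parentA").reindex(keep, fill_value=0.0),
        run.counts("parentB").reindex(keep, fill_value=0.0),
        run.counts("hybrid").reindex(keep, fill_value=0.0),
        hybrid_ploidy=3 if sum(dosage) == 3 else 2,
    )
    scored = [r for r in records if r.expected >= 4.0]
    return {
        "deviation_scores": table,
        "summary": {
            "cumulative_score": float(sum(r.score for r in scored)),
            "n_scored_clusters": len(scored),
            "family_means": family_mean_scores(records),
            "novel_clusters": novel,
            "intermediacy": {
                "mean_delta_parentA": inter.mean_delta1,
                "mean_delta_parentB": inter.mean_delta2,
                "delta": inter.delta,
                "p_value": inter.p_value,
                "closer_parent": inter.closer_parent,
            },
        },
    }


def individual_mode(manifest: dict, seed: int) -> dict:
    from .annotate import (
        AnnotationParams,
        annotate_cluster,
        domain_db_from_families,
        propagate_supercluster_annotation,
    )
    from .report import composition_table
    from .simulate import demo_families, full_parent_specs

    genome_length = int(manifest.get("genome_length", 1_000_000))
    coverage = float(manifest.get("coverage", 0.4))
    spec_a, _ = full_parent_specs(genome_length=genome_length)
    g = build_parental_genome(spec_a, derive_seed(seed, 301))
    rs = simulate_reads(
        g,
        ReadSimParams(coverage=coverage),
        derive_seed(seed, 302),
        sample=spec_a.label,
    )
    rs = quality_filter(rs)
    datasets = {spec_a.label: rs.with_id_prefix(f"{spec_a.label}:").with_sample(spec_a.label)}
    joint = datasets[spec_a.label]
    graph = build_similarity_graph(joint, SimilarityParams())
    clus = ClusteringParams(seed=seed)
    clusters, singlets = partition_clusters(graph, clus)
    above, below = apply_size_threshold(clusters, joint.n_reads, clus)
    superclusters = build_superclusters(above, clus)
    sample_of_read = {}
    seq_of_read = {}
    for p in joint:
        for mate, seq in ((1, p.seq1), (2, p.seq2)):
            sample_of_read[f"{p.id}/{mate}"] = p.sample
            seq_of_read[f"{p.id}/{mate}"] = seq
    totals = {spec_a.label: joint.n_reads}
    ab = quantify_clusters(above, sample_of_read, totals)
    db = domain_db_from_families(demo_families().values())
    anns = {
        c.id: annotate_cluster(c, seq_of_read, db, AnnotationParams()).lineage
        for c in above
    }
    eff = propagate_supercluster_annotation(superclusters, above, anns)
    below_n = sum(c.size for c in below)
    comp_table = composition_table(
        ab,
        eff,
        {spec_a.label: below_n / joint.n_reads},
        {spec_a.label: len(singlets) / joint.n_reads},
    )
    return {"composition": comp_table, "summary": {
        "n_clusters_above": len(above),
        "n_superclusters": len(superclusters),
        "n_singlets": len(singlets),
    }}


def bias_mode(manifest: dict, seed: int) -> dict:
    tiers = manifest.get("tiers", ["intra_library", "inter_specific"])
    n_seeds = int(manifest.get("n_seeds", 3))
    runs = []
    for t in tiers:
        for k in range(n_seeds):
            p1, p2 = bias_tier_pair(
                derive_seed(seed, 400 + k),
                t,
                subsample_pairs=int(manifest.get("subsample_pairs", 800)),
                genome_length=int(manifest.get("genome_length", 1_000_000)),
            )
            runs.append((t, p1, p2))
    comparisons, tests = comp.bias_assessment(runs)
    means = pd.DataFrame(
        [{"tier": c.tier, "mean_percent_difference": c.mean} for c in comparisons]
    )
    return {"tier_means": means, "tier_tests": tests}
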