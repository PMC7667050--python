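"""Graph-based clustering of reads into repeat families.

Reads are vertices; an edge connects two reads whose best local alignment
covers at least 55 % of the shorter read at 90 % identity or better
(either strand).  Connected communities of the graph are repeat clusters;
clusters linked by split mate pairs form superclusters.  This mirrors the
clustering stage of low-coverage repeatome pipelines, with connected
components as the default, fully deterministic community definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import _simgraph
from ._align import GAP, MATCH, MISMATCH, _sw, encode, revcomp_codes
from .core import ReadSet


@dataclass(frozen=True)
class SimilarityParams:
    """The similarity rule: identity over a minimum fraction of the read."""

    min_identity: float = 0.90
    min_length_fraction: float = 0.55
    both_strands: bool = True
    gapless_screen_min: int = 30  # candidate gate; 0 disables (see _simgraph)

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_length_fraction <= 1:
            raise ValueError("min_length_fraction must be in (0, 1]")

    def min_span(self, shorter_len: int) -> int:
        return int(math.ceil(self.min_length_fraction * shorter_len - 1e-9))


@dataclass(frozen=True)
class ClusteringParams:
    size_threshold: float = 0.0001  # fraction of total input reads (0.01 %)
    supercluster_ratio: float = 0.1
    community_method: str = "connected_components"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.size_threshold < 1:
            raise ValueError("size_threshold must be in [0, 1)")
        if self.supercluster_ratio <= 0:
            raise ValueError("supercluster_ratio must be > 0")
        if self.community_method not in ("connected_components", "modularity"):
            raise ValueError(f"unknown community_method {self.community_method!r}")


@dataclass
class Cluster:
    id: int
    read_ids: frozenset[str]
    size: int
    proportion: float
    contigs: list[str] = field(default_factory=list)
    annotation: str = "unclassified"


@dataclass
class Supercluster:
    id: int
    member_cluster_ids: frozenset[int]
    annotation: str = "unclassified"


# ------------------------------------------------------------------ similarity


def _qualify(a: np.ndarray, b: np.ndarray, p: SimilarityParams) -> bool:
    score, matches, cols, ab, ae, bb, be = _sw(a, b, MATCH, MISMATCH, GAP)
    if cols == 0:
        return False
    span = (ae - ab) if a.shape[0] <= b.shape[0] else (be - bb)
    return span >= p.min_span(min(a.shape[0], b.shape[0])) and (
        matches >= p.min_identity * cols - 1e-9
    )


def pairwise_similar(r1: str, r2: str, p: SimilarityParams) -> bool:
    """Decide similarity of two reads by full Smith-Waterman.

    The pair is evaluated in a canonical frame (lexicographically smaller
    sequence first) so the predicate is exactly symmetric, including any
    tie-breaking inside the aligner.  This is the reference predicate the
    production graph builder must agree with.
    """
    if not r1 or not r2:
        raise ValueError("empty sequence")
    a, b = sorted((r1.upper(), r2.upper()))
    ca, cb = encode(a), encode(b)
    if _qualify(ca, cb, p):
        return True
    if p.both_strands:
        return _qualify(ca, revcomp_codes(cb), p)
    return False


def _read_vertices(reads: ReadSet) -> tuple[list[str], list[str]]:
    ids: list[str] = []
    seqs: list[str] = []
    for pair in reads:
        ids.append(f"{pair.id}/1")
        seqs.append(pair.seq1)
        ids.append(f"{pair.id}/2")
        seqs.append(pair.seq2)
    return ids, seqs


def _encode_matrix(seqs: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lens = np.array([len(s) for s in seqs], np.int32)
    L = int(lens.max())
    codes = np.full((len(seqs), L), 4, np.uint8)
    rc = np.full((len(seqs), L), 4, np.uint8)
    for i, s in enumerate(seqs):
        c = encode(s)
        codes[i, : lens[i]] = c
        rc[i, : lens[i]] = revcomp_codes(c)
    return codes, rc, lens


def build_similarity_graph(reads: ReadSet, p: SimilarityParams) -> nx.Graph:
    """Similarity graph over individual reads (mates are separate vertices).

    Uses the lossless shared-9-mer candidate join plus the gapless-diagonal
    gate of :mod:`repeatome._simgraph`; on substitution-dominated data the
    edge set equals the all-pairs :func:`pairwise_similar` graph.
    """
    ids, seqs = _read_vertices(reads)
    if len(ids) < 2:
        raise ValueError("need at least 2 reads")
    codes, rc, lens = _encode_matrix(seqs)
    lex_order = sorted(range(len(seqs)), key=lambda i: seqs[i])
    lex_rank = np.empty(len(seqs), np.int64)
    for rank, i in enumerate(lex_order):
        lex_rank[i] = rank
    ei, ej = _simgraph.candidate_edges(
        codes,
        lens,
        rc,
        lex_rank,
        p.min_identity,
        p.min_length_fraction,
        p.gapless_screen_min,
        p.both_strands,
    )
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from((ids[int(i)], ids[int(j)]) for i, j in zip(ei, ej))
    return g


def brute_force_graph(reads: ReadSet, p: SimilarityParams) -> nx.Graph:
    """All-pairs oracle graph; quadratic, for verification on small inputs."""
    ids, seqs = _read_vertices(reads)
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_similar(seqs[i], seqs[j], p):
                g.add_edge(ids[i], ids[j])
    return g


# ------------------------------------------------------------------ clustering


def partition_clusters(
    graph: nx.Graph, p: ClusteringParams
) -> tuple[list[Cluster], list[str]]:
    """Partition the graph into clusters (communities of size >= 2) + singlets.

    Cluster ids are 1-based in decreasing size order, ties broken by the
    smallest member read id, so output is stable under read relabeling.
    """
    total = graph.number_of_nodes()
    communities: list[set] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        if p.community_method == "modularity" and len(comp) > 3:
            sub = graph.subgraph(comp)
            for com in nx.community.greedy_modularity_communities(sub):
                communities.append(set(com))
        else:
            communities.append(set(comp))
    communities.sort(key=lambda c: (-len(c), min(c)))
    clusters = []
    clustered: set[str] = set()
    for k, com in enumerate(communities, start=1):
        clusters.append(
            Cluster(
                id=k,
                read_ids=frozenset(com),
                size=len(com),
                proportion=len(com) / total,
            )
        )
        clustered |= com
    singlets = sorted(n for n in graph.nodes if n not in clustered)
    return clusters, singlets


def apply_size_threshold(
    clusters: list[Cluster], total_reads: int, p: ClusteringParams
) -> tuple[list[Cluster], list[Cluster]]:
    """Split clusters at the abundance threshold (default 0.01 % of input).

    A cluster passes when its size is at least ``size_threshold *
    total_reads`` reads; the rest are the "small uncharacterized" mass.
    """
    cut = p.size_threshold * total_reads
    above = [c for c in clusters if c.size >= cut]
    below = [c for c in clusters if c.size < cut]
    return above, below


def _mate_id(read_id: str) -> str:
    base, mate = read_id.rsplit("/", 1)
    return f"{base}/{'2' if mate == '1' else '1'}"


def build_superclusters(
    clusters: list[Cluster], p: ClusteringParams
) -> list[Supercluster]:
    """Group clusters that share split mate pairs.

    Clusters X and Y merge when shared(X,Y) / (unpaired(X) + unpaired(Y))
    is *strictly* greater than the ratio threshold, where shared counts
    mate pairs split between X and Y and unpaired counts reads whose mate
    lies outside their own cluster.  Superclusters are the transitive
    closure of merges.
    """
    of_cluster: dict[str, int] = {}
    for c in clusters:
        for rid in c.read_ids:
            of_cluster[rid] = c.id
    unpaired: dict[int, int] = {c.id: 0 for c in clusters}
    shared: dict[tuple[int, int], int] = {}
    for c in clusters:
        for rid in c.read_ids:
            mate = _mate_id(rid)
            if mate in c.read_ids:
                continue
            unpaired[c.id] += 1
            other = of_cluster.get(mate)
            if other is not None and other > c.id:
                shared[(c.id, other)] = shared.get((c.id, other), 0) + 1
    merge = nx.Graph()
    merge.add_nodes_from(unpaired)
    for (x, y), s in shared.items():
        denom = unpaired[x] + unpaired[y]
        assert denom > 0, "shared pairs imply unpaired reads in both clusters"
        if s / denom > p.supercluster_ratio:
            merge.add_edge(x, y)
    comps = sorted(nx.connected_components(merge), key=lambda c: min(c))
    return [
        Supercluster(id=k, member_cluster_ids=frozenset(comp))
        for k, comp in enumerate(comps, start=1)
    ]


def quantify_clusters(
    clusters: list[Cluster],
    sample_of_read: dict[str, str],
    totals: dict[str, int],
) -> pd.DataFrame:
    """Per-sample, per-cluster read counts and within-sample proportions.

    ``totals`` gives each sample's total input reads (the proportion
    denominator), so cluster proportions plus the singlet fraction close
    to 1 per sample.
    """
    rows = []
    for c in clusters:
        counts: dict[str, int] = {}
        for rid in c.read_ids:
            try:
                s = sample_of_read[rid]
            except KeyError:
                raise KeyError(f"read {rid} has no sample assignment") from None
            counts[s] = counts.get(s, 0) + 1
        for s in totals:
            n = counts.get(s, 0)
            rows.append(
                {
                    "cluster_id": c.id,
                    "sample": s,
                    "count": n,
                    "proportion": n / totals[s],
                }
            )
        unknown = set(counts) - set(totals)
        if unknown:
            raise KeyError(f"unknown sample prefix(es) {sorted(unknown)}")
    return pd.DataFrame(rows, columns=["cluster_id", "sample", "count", "proportion"])


# --------------------------------------------------------------------- contigs


def _place(contig_votes, consensus, read_codes, p, min_overlap):
    """Try to align a read (given orientation) onto the working consensus."""
    score, matches, cols, cb, ce, rb, re_ = _sw(
        consensus, read_codes, MATCH, MISMATCH, GAP
    )
    if cols == 0:
        return None
    overlap = re_ - rb
    if overlap < min_overlap or matches < 0.9 * cols - 1e-9:
        return None
    offset = cb - rb  # assume substitution-dominated placement
    return offset


def assemble_contigs(
    cluster: Cluster,
    seq_of_read: dict[str, str],
    min_overlap: int = 30,
    max_reads: int = 400,
) -> list[str]:
    """Greedy overlap-layout-consensus contigs for one cluster.

    Seeds from the first unplaced read (stable id order), then repeatedly
    places reads overlapping the working consensus by >= ``min_overlap``
    bases at >= 90 % identity (either orientation), extending it with
    per-column majority votes.  Simplified on purpose: contigs need not
    tile the whole family.
    """
    rids = sorted(cluster.read_ids)[:max_reads]
    reads = {r: encode(seq_of_read[r]) for r in rids}
    unplaced = list(rids)
    contigs: list[str] = []
    while unplaced:
        seed = unplaced.pop(0)
        codes = reads[seed]
        votes = [
            [1 if b == codes[i] else 0 for b in range(4)]
            for i in range(codes.shape[0])
        ]
        consensus = codes.copy()
        placed_any = True
        while placed_any:
            placed_any = False
            for rid in list(unplaced):
                rc = reads[rid]
                hit = None
                for oriented in (rc, revcomp_codes(rc)):
                    off = _place(votes, consensus, oriented, None, min_overlap)
                    if off is not None:
                        hit = (oriented, off)
                        break
                if hit is None:
                    continue
                oriented, off = hit
                L = oriented.shape[0]
                if off < 0:
                    votes = [[0, 0, 0, 0] for _ in range(-off)] + votes
                    off = 0
                while len(votes) < off + L:
                    votes.append([0, 0, 0, 0])
                for t in range(L):
                    votes[off + t][oriented[t]] += 1
                consensus = np.array(
                    [int(np.argmax(v)) for v in votes], dtype=np.uint8
                )
                unplaced.remove(rid)
                placed_any = True
        bases = "ACGT"
        contigs.append("".join(bases[int(np.argmax(v))] for v in votes))
    return contigs


def cluster_truth_majority(cluster: Cluster, truth_of_read: dict[str, str]) -> str:
    """Ground-truth family owning the majority of a cluster's reads."""
    counts: dict[str, int] = {}
    for rid in cluster.read_ids:
        t = truth_of_read.get(rid, "unknown")
        counts[t] = counts.get(t, 0) + 1
    return max(counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
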