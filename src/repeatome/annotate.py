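"""Cluster annotation, tandem-monomer detection and read screening.

Clusters are labeled by the lineage of the reference "domain" exemplars
their reads hit (nucleotide space, same 90 %/55 % similarity rule as the
clustering); unannotated clusters inside a supercluster inherit the
supercluster's majority lineage.  Tandem monomers are found by maximizing
the base-match autocorrelation of a contig over candidate lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from ._align import GAP, MATCH, MISMATCH, _sw, encode, revcomp_codes
from ._simgraph import KMER, _kadane_diag
from .cluster import Cluster, SimilarityParams, Supercluster
from .core import ReadSet


@dataclass(frozen=True)
class AnnotationParams:
    min_hit_fraction: float = 0.05
    same_lineage_required: bool = True

    def __post_init__(self):
        if not 0 < self.min_hit_fraction <= 1:
            raise ValueError("min_hit_fraction must be in (0, 1]")


@dataclass(frozen=True)
class AnnotationResult:
    lineage: str  # "unclassified" when below threshold
    hit_fraction: float
    conflict: bool = False


@dataclass(frozen=True)
class TandemReport:
    monomer_length: int
    monomer_consensus: str
    copies_in_contig: float
    array_span: int


# ------------------------------------------------------------ reference search


@njit(cache=True)
def _ref_kmer_table(ref_codes, k):
    L = ref_codes.shape[0]
    n = L - k + 1
    km = np.empty(n, np.int64)
    pos = np.empty(n, np.int32)
    ori = np.empty(n, np.uint8)
    mask = (1 << (2 * k)) - 1
    f = 0
    r = 0
    for t in range(k):
        f = (f << 2) | ref_codes[t]
        r |= (3 - ref_codes[t]) << (2 * t)
    p = 0
    idx = 0
    while True:
        c = f if f <= r else r
        km[idx] = c
        pos[idx] = p
        ori[idx] = 0 if f <= r else 1
        idx += 1
        if p + k >= L:
            break
        nxt = ref_codes[p + k]
        f = ((f << 2) | nxt) & mask
        r = (r >> 2) | ((3 - nxt) << (2 * (k - 1)))
        p += 1
    return km, pos, ori


class ReferenceIndex:
    """Shared-9-mer index of one reference sequence for read screening."""

    def __init__(self, seq: str):
        self.codes = encode(seq)
        self.rc_codes = revcomp_codes(self.codes)
        self.length = self.codes.shape[0]
        km, pos, ori = _ref_kmer_table(self.codes, KMER)
        order = np.argsort(km, kind="stable")
        self._km = km[order]
        self._pos = pos[order]
        self._ori = ori[order]

    def _candidate_diagonals(self, read_codes: np.ndarray):
        """(strand, diagonal) seeds shared between read and reference."""
        L = read_codes.shape[0]
        k = KMER
        out: dict[tuple[int, int], int] = {}
        mask = (1 << (2 * k)) - 1
        f = 0
        r = 0
        for t in range(k):
            f = (f << 2) | int(read_codes[t])
            r |= (3 - int(read_codes[t])) << (2 * t)
        p = 0
        while True:
            c = f if f <= r else r
            o_read = 0 if f <= r else 1
            lo = int(np.searchsorted(self._km, c, side="left"))
            hi = int(np.searchsorted(self._km, c, side="right"))
            for t in range(lo, hi):
                s = o_read ^ int(self._ori[t])
                rp = int(self._pos[t])
                if s == 1:
                    rp = self.length - k - rp
                key = (s, p - rp)
                out[key] = out.get(key, 0) + 1
            if p + k >= L:
                break
            nxt = int(read_codes[p + k])
            f = ((f << 2) | nxt) & mask
            r = (r >> 2) | ((3 - nxt) << (2 * (k - 1)))
            p += 1
        return out

    def read_hits(
        self, read_codes: np.ndarray, sim: SimilarityParams, pad: int = 30
    ) -> bool:
        """Does the read match the reference under the similarity rule?

        Seeded diagonals are gated by their best gapless run, then the
        alignment is confirmed by Smith-Waterman of the read against a
        reference window around the diagonal.
        """
        L = read_codes.shape[0]
        min_span = sim.min_span(min(L, self.length))
        cands = []
        for (s, d), _ in self._candidate_diagonals(read_codes).items():
            ref = self.codes if s == 0 else self.rc_codes
            g = _kadane_diag(read_codes, L, ref, self.length, d, MATCH, MISMATCH)
            if sim.gapless_screen_min <= 0 or g >= sim.gapless_screen_min:
                cands.append((-g, s, d))
        cands.sort()
        seen: set[tuple[int, int]] = set()
        for _, s, d in cands[:8]:
            key = (s, d // 25)
            if key in seen:
                continue
            seen.add(key)
            ref = self.codes if s == 0 else self.rc_codes
            lo = max(0, -d - pad)
            hi = min(self.length, -d + L + pad)
            if hi - lo < KMER:
                continue
            window = np.ascontiguousarray(ref[lo:hi])
            score, matches, cols, ab, ae, bb, be = _sw(
                read_codes, window, MATCH, MISMATCH, GAP
            )
            if cols == 0:
                continue
            # span is measured on the shorter of read vs full reference
            span = (ae - ab) if L <= self.length else (be - bb)
            if span >= min_span and matches >= sim.min_identity * cols - 1e-9:
                return True
        return False


def match_reads_to_references(
    seqs: list[str], refs: dict[str, str], sim: SimilarityParams | None = None
) -> np.ndarray:
    """Boolean matrix: seqs x references, under the similarity rule."""
    if not refs:
        raise ValueError("empty reference set")
    sim = sim or SimilarityParams()
    idxs = {name: ReferenceIndex(seq) for name, seq in refs.items()}
    out = np.zeros((len(seqs), len(refs)), bool)
    for i, s in enumerate(seqs):
        codes = encode(s)
        for j, name in enumerate(refs):
            out[i, j] = idxs[name].read_hits(codes, sim)
    return out


def reads_match_references(
    reads: ReadSet, refs: dict[str, str], sim: SimilarityParams | None = None
) -> list[bool]:
    """Per-pair flag: does either mate match any reference?"""
    seqs: list[str] = []
    for p in reads:
        seqs.append(p.seq1)
        seqs.append(p.seq2)
    m = match_reads_to_references(seqs, refs, sim)
    any_ref = m.any(axis=1)
    return [bool(any_ref[2 * i] or any_ref[2 * i + 1]) for i in range(len(reads))]


def screen_reads_by_reference(
    reads: ReadSet, refs: dict[str, str], sim: SimilarityParams | None = None
) -> dict[str, float]:
    """Genomic proportion (%) of reads matching each reference.

    Counts individual reads (each read once per reference); this is the
    whole-dataset cross-check that can detect repeats too rare to form an
    above-threshold cluster.
    """
    seqs: list[str] = []
    for p in reads:
        seqs.append(p.seq1)
        seqs.append(p.seq2)
    if not seqs:
        return {name: 0.0 for name in refs}
    m = match_reads_to_references(seqs, refs, sim)
    return {
        name: 100.0 * float(m[:, j].sum()) / len(seqs)
        for j, name in enumerate(refs)
    }


# ------------------------------------------------------------------ annotation


def annotate_cluster(
    cluster: Cluster,
    seq_of_read: dict[str, str],
    domain_db: dict[str, tuple[str, str]],
    p: AnnotationParams | None = None,
    sim: SimilarityParams | None = None,
) -> AnnotationResult:
    """Label a cluster by its reads' domain hits.

    ``domain_db`` maps exemplar name -> (sequence, lineage).  The cluster
    gets the lineage with the largest fraction of reads hitting any of
    its exemplars, provided that fraction reaches ``min_hit_fraction``;
    two lineages above threshold mark a conflict (larger one wins).
    """
    if not domain_db:
        raise ValueError("empty domain database")
    p = p or AnnotationParams()
    sim = sim or SimilarityParams()
    rids = sorted(cluster.read_ids)
    seqs = [seq_of_read[r] for r in rids]
    refs = {name: seq for name, (seq, _) in domain_db.items()}
    m = match_reads_to_references(seqs, refs, sim)
    lineages = sorted({lin for _, lin in domain_db.values()})
    frac: dict[str, float] = {}
    for lin in lineages:
        cols = [j for j, name in enumerate(refs) if domain_db[name][1] == lin]
        hits = m[:, cols].any(axis=1).sum()
        frac[lin] = float(hits) / cluster.size
    qualifying = {k: v for k, v in frac.items() if v >= p.min_hit_fraction - 1e-12}
    if not qualifying:
        return AnnotationResult("unclassified", max(frac.values(), default=0.0))
    best = max(qualifying.items(), key=lambda kv: (kv[1], kv[0]))
    return AnnotationResult(best[0], best[1], conflict=len(qualifying) > 1)


def propagate_supercluster_annotation(
    superclusters: list[Supercluster],
    clusters: list[Cluster],
    cluster_annotations: dict[int, str],
) -> dict[int, str]:
    """Supercluster-level annotations: unannotated members inherit.

    The supercluster's lineage is the majority by total reads of its
    annotated member clusters; annotated members always keep their own
    label (propagation never overwrites an annotation).  Ties leave the
    members unclassified with a warning.
    """
    size_of = {c.id: c.size for c in clusters}
    effective = dict(cluster_annotations)
    for sc in superclusters:
        weights: dict[str, int] = {}
        for cid in sc.member_cluster_ids:
            lin = cluster_annotations.get(cid, "unclassified")
            if lin != "unclassified":
                weights[lin] = weights.get(lin, 0) + size_of.get(cid, 0)
        if not weights:
            continue
        ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            warnings.warn(
                f"supercluster {sc.id}: tied lineages {ranked[0][0]}/{ranked[1][0]}",
                stacklevel=2,
            )
            continue
        majority = ranked[0][0]
        for cid in sc.member_cluster_ids:
            if effective.get(cid, "unclassified") == "unclassified":
                effective[cid] = majority
    return effective


# -------------------------------------------------------------- tandem repeats


@njit(cache=True)
def _lag_match(arr, lag):
    n = arr.shape[0] - lag
    hits = 0
    for i in range(n):
        if arr[i] == arr[i + lag]:
            hits += 1
    return hits / n if n > 0 else 0.0


def detect_tandem_monomer(
    contig: str, min_match: float = 0.8, min_copies: float = 1.5
) -> TandemReport | None:
    """Find a tandem monomer by base-match autocorrelation.

    Scans lags 2..len/2 and reports the *smallest* lag whose self-match
    fraction reaches ``min_match`` with at least ``min_copies`` copies in
    the contig (smallest lag = the monomer, not a multiple).  The monomer
    consensus is the column majority over phased copies.
    """
    if len(contig) < 50:
        return None
    arr = encode(contig)
    L = arr.shape[0]
    best_lag = 0
    for lag in range(2, L // 2 + 1):
        if L / lag < min_copies:
            break
        if _lag_match(arr, lag) >= min_match - 1e-12:
            best_lag = lag
            break
    if best_lag == 0:
        return None
    k = best_lag
    cons = np.empty(k, np.uint8)
    for c in range(k):
        votes = np.zeros(4, np.int64)
        for t in range(c, L, k):
            votes[arr[t]] += 1
        cons[c] = int(np.argmax(votes))
    bases = "ACGT"
    return TandemReport(
        monomer_length=k,
        monomer_consensus="".join(bases[int(b)] for b in cons),
        copies_in_contig=L / k,
        array_span=L,
    )


# ------------------------------------------------------------------ categories

_CATEGORY_RULES: list[tuple[tuple[str, ...], str]] = [
    (("ty1/copia", "sire", "angela", "ale", "bianca", "ikeros", "tar", "tork",
      "maximus"), "Ty1/Copia"),
    (("ty3/gypsy", "tekay", "crm", "chromovirus", "athila", "ogre", "tat"),
     "Ty3/Gypsy"),
    (("pararetrovirus",), "pararetrovirus"),
    (("helitron",), "Helitron"),
    (("dna-transposon", "dna transposon", "cacta", "enspm", "hat", "mudr",
      "mutator", "pif", "harbinger"), "DNA transposons"),
    (("satellite", "sat"), "satellite DNA"),
    (("45s",), "45S rDNA"),
    (("5s",), "5S rDNA"),
]


def classify_category(lineage: str) -> str:
    """Map a fine lineage label to its reporting category.

    Unknown labels fall back to "unclassified" with a warning, so the
    category totals always partition the label set.
    """
    low = lineage.lower()
    if low in ("unclassified", "background", ""):
        return "unclassified"
    for keys, cat in _CATEGORY_RULES:
        for key in keys:
            if key in low:
                return cat
    warnings.warn(f"unknown lineage {lineage!r}; classified as unclassified",
                  stacklevel=2)
    return "unclassified"


def domain_db_from_families(families) -> dict[str, tuple[str, str]]:
    """Build a nucleotide domain database from simulated repeat families."""
    db: dict[str, tuple[str, str]] = {}
    for fam in families:
        for k, (s, e, lin) in enumerate(fam.domain_segments):
            db[f"{fam.name}.dom{k}"] = (fam.consensus[s:e], lin)
        if fam.monomer_length is not None:
            db[f"{fam.name}.monomer"] = (fam.consensus, fam.lineage)
    return db
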