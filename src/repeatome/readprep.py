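"""Read pre-processing: quality, pair conformance, overlap, organelle,
in-silico parent pooling and coverage-equalized subsampling.

All filters operate on whole mate pairs (a pair survives only if both
mates pass) and are idempotent.  Subsampling is what makes comparative
runs commensurable: every sample is cut down to the same per-1C coverage,
so cluster read counts measure absolute repeat DNA amounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from ._align import encode
from .core import ReadPair, ReadSet


@dataclass(frozen=True)
class QCParams:
    """Quality rule: >= 95 % of bases at Phred >= 10, no Ns, fixed length."""

    phred_min: int = 10
    min_fraction_at_phred: float = 0.95
    allow_ambiguous: bool = False
    required_length: int = 150

    def __post_init__(self):
        if not 0 < self.min_fraction_at_phred <= 1:
            raise ValueError("min_fraction_at_phred must be in (0, 1]")


@dataclass(frozen=True)
class SampleMeta:
    """Sample sheet row: ploidy, genome size, role and parental dosage."""

    id: str
    species: str
    ploidy: int
    size_2C_pg: float
    role: str  # parent | natural_hybrid | synthetic_hybrid
    dosage: tuple[int, int] | None = None
    library_id: str = ""

    def __post_init__(self):
        if self.size_2C_pg <= 0:
            raise ValueError("size_2C_pg must be > 0")
        if self.ploidy not in (2, 3):
            raise ValueError("ploidy must be 2 or 3")
        is_hybrid = self.role in ("natural_hybrid", "synthetic_hybrid")
        if is_hybrid and self.dosage is None:
            raise ValueError(f"sample {self.id}: hybrid role requires a dosage")
        if not is_hybrid and self.dosage is not None:
            raise ValueError(f"sample {self.id}: parent must not carry a dosage")

    def g1c_bp(self, round_gbp_dp: int | None = None) -> float:
        """Holoploid 1C size in bp (1 pg = 0.978 Gbp), optionally rounded
        to the precision genome-size tables are printed at."""
        g = self.size_2C_pg / 2 * 0.978  # Gbp
        if round_gbp_dp is not None:
            g = round(g, round_gbp_dp)
        return g * 1e9


def _mate_ok(seq: str, qual: str, q: QCParams, read_id: str) -> bool:
    if len(seq) != len(qual):
        raise ValueError(f"read {read_id}: sequence/quality length mismatch")
    if len(seq) != q.required_length:
        return False
    if not q.allow_ambiguous and ("N" in seq or "n" in seq):
        return False
    need = math.ceil(q.min_fraction_at_phred * len(seq) - 1e-9)
    good = sum(1 for c in qual if ord(c) - 33 >= q.phred_min)
    return good >= need


def quality_filter(reads: ReadSet, q: QCParams | None = None) -> ReadSet:
    """Keep pairs where both mates meet the quality rule."""
    q = q or QCParams()
    kept = [
        p
        for p in reads
        if _mate_ok(p.seq1, p.qual1, q, f"{p.id}/1")
        and _mate_ok(p.seq2, p.qual2, q, f"{p.id}/2")
    ]
    return ReadSet(kept)


@njit(cache=True)
def _best_terminal_overlap(a, b, min_overlap, min_identity):
    """Longest suffix(a)/prefix(b) Hamming overlap meeting the identity bar."""
    la = a.shape[0]
    lb = b.shape[0]
    omax = la if la < lb else lb
    for o in range(omax, min_overlap - 1, -1):
        m = 0
        for t in range(o):
            if a[la - o + t] == b[t]:
                m += 1
        if m >= min_identity * o - 1e-9:
            return o
    return 0


def overlap_filter(
    reads: ReadSet, min_overlap: int = 20, min_identity: float = 0.90
) -> ReadSet:
    """Drop pairs whose mates overlap (insert shorter than two reads).

    Mate 1 and the reverse complement of mate 2 are checked for a terminal
    (suffix/prefix) overlap of at least ``min_overlap`` bases at
    ``min_identity``; such pairs carry redundant sequence and are removed
    to maximize genome representation.
    """
    from ._align import revcomp

    kept = []
    for p in reads:
        a = encode(p.seq1)
        b = encode(revcomp(p.seq2))
        if _best_terminal_overlap(a, b, min_overlap, min_identity) == 0:
            kept.append(p)
    return ReadSet(kept)


def organelle_filter(
    reads: ReadSet, organelle_refs: dict[str, str], sim=None
) -> tuple[ReadSet, ReadSet, float]:
    """Split pairs into nuclear and organellar by reference screening.

    A pair is organellar when either mate matches any reference under the
    standard similarity rule (90 % identity over 55 % of the read).
    Returns (nuclear, organellar, fraction removed).
    """
    from .annotate import reads_match_references
    from .cluster import SimilarityParams

    if not organelle_refs:
        raise ValueError("empty organelle reference")
    sim = sim or SimilarityParams()
    hits = reads_match_references(reads, organelle_refs, sim)
    nuclear, organelle = [], []
    for p, h in zip(reads, hits):
        (organelle if h else nuclear).append(p)
    frac = len(organelle) / len(reads) if len(reads) else 0.0
    return ReadSet(nuclear), ReadSet(organelle), frac


def pool_in_silico_parent(sets: list[ReadSet], label: str) -> ReadSet:
    """Pool libraries into an in-silico parent, preserving provenance.

    Read ids are prefixed with their source index when they would collide.
    """
    if not sets:
        raise ValueError("need at least one read set")
    seen: set[str] = set()
    out: list[ReadPair] = []
    for k, rs in enumerate(sets):
        for p in rs:
            rid = p.id
            if rid in seen:
                rid = f"{label}.{k}.{p.id}"
            seen.add(rid)
            out.append(replace(p, id=rid))
    return ReadSet(out)


def subsample_size(target_coverage: float, g1c_bp: float, read_length: int) -> int:
    """Number of individual reads for a target 1C coverage (rounded to pairs)."""
    n = round(target_coverage * g1c_bp / read_length)
    n_pairs = int(round(n / 2))
    return 2 * n_pairs


def subsample_to_coverage(
    reads: ReadSet,
    meta: SampleMeta,
    target_coverage: float,
    read_length: int = 150,
    seed: int = 0,
    g1c_bp: float | None = None,
) -> ReadSet:
    """Uniform subsample to an exact per-1C coverage.

    ``g1c_bp`` overrides the genome size derived from ``meta`` (useful
    when matching a printed genome-size table).  Pairs are kept intact;
    sampling is without replacement and deterministic under ``seed``.
    """
    g1c = g1c_bp if g1c_bp is not None else meta.g1c_bp()
    n = subsample_size(target_coverage, g1c, read_length)
    n_pairs = n // 2
    if n_pairs > len(reads):
        raise ValueError(
            f"sample {meta.id}: requested {n_pairs} pairs, only {len(reads)} "
            f"available (deficit {n_pairs - len(reads)})"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=n_pairs, replace=False))
    return ReadSet(reads[int(i)] for i in idx)
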