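"""Synthetic parental and hybrid repeatomes with known ground truth.

The generator emulates the study design this package targets: two diploid
parental species whose genomes share the same medium/high-abundance repeat
families at slightly different copy numbers, and hybrids that combine the
parental monoploid complements at an integer dosage (2:1, 1:2 or 1:1),
optionally with a per-family amplification ("burst") or loss.  Paired-end
150 bp reads with ~450 bp inserts and substitution errors are then drawn
uniformly from the genome, each pair carrying a truth tag naming the
repeat family its fragment came from.

Copy divergence is applied as i.i.d. substitutions only (no indels), which
keeps every repeat copy the same length as its consensus and makes the
truth accounting and the alignment oracle exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import encode, revcomp_codes
from .core import BACKGROUND, ReadPair, ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (reproducible bursts)."""
    return int(math.floor(x + 0.5))


# --------------------------------------------------------------------- types


@dataclass(frozen=True)
class RepeatFamily:
    """A repeat family: consensus sequence plus lineage metadata.

    ``lineage`` is a hierarchical label such as ``"Ty1/Copia:SIRE"`` or
    ``"satellite:CL229"``; ``monomer_length`` is set for tandem families
    only; ``domain_segments`` marks (start, end, lineage) intervals on the
    consensus that stand in for protein-domain exemplars.
    """

    name: str
    lineage: str
    consensus: str
    monomer_length: int | None = None
    domain_segments: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self):
        if not self.consensus or set(self.consensus.upper()) - set("ACGT"):
            raise ValueError(f"family {self.name}: consensus must be nonempty ACGT")
        L = len(self.consensus)
        for s, e, _ in self.domain_segments:
            if not (0 <= s < e <= L):
                raise ValueError(f"family {self.name}: domain segment out of bounds")
        if self.monomer_length is not None and self.monomer_length > L:
            raise ValueError(f"family {self.name}: monomer longer than consensus")


@dataclass(frozen=True)
class GenomeComponent:
    family: RepeatFamily
    copy_number: int
    divergence: float = 0.0

    def __post_init__(self):
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if not 0 <= self.divergence <= 0.1:
            raise ValueError("divergence must be in [0, 0.1]")


@dataclass(frozen=True)
class GenomeSpec:
    """Monoploid (1Cx) composition of one parental genome."""

    label: str
    components: tuple[GenomeComponent, ...]
    background_length: int = 0

    def __post_init__(self):
        if self.total_length() <= 0:
            raise ValueError("empty genome")

    def total_length(self) -> int:
        return self.background_length + sum(
            c.copy_number * len(c.family.consensus) for c in self.components
        )


@dataclass(frozen=True)
class HybridSpec:
    """A hybrid as an integer dosage of two parental monoploid genomes."""

    label: str
    parentA_spec: GenomeSpec
    parentB_spec: GenomeSpec
    dosage: tuple[int, int]
    bursts: tuple[tuple[str, float], ...] = ()  # (family name, factor > 0)

    def __post_init__(self):
        d_a, d_b = self.dosage
        if d_a < 0 or d_b < 0:
            raise ValueError("negative dosage")
        if d_a + d_b < 2:
            raise ValueError("dosage components must sum to >= 2")
        for name, a in self.bursts:
            if a <= 0:
                raise ValueError(f"burst factor for {name} must be > 0")


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 150
    insert_mean: float = 450.0
    insert_sd: float = 60.0
    error_rate: float = 0.005
    coverage: float = 0.1
    quality_correct: int = 35
    quality_error: int = 10

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class Genome:
    """A concrete genome sequence with per-segment truth labels.

    ``c1_length`` is the holoploid (1C) size in bases: equal to the
    sequence length for a parental monoploid build, and half of it for a
    hybrid build (whose sequence is the full 2C complement).
    """

    label: str
    codes: np.ndarray
    seg_bounds: np.ndarray  # cumulative segment end positions
    seg_labels: list[str]
    c1_length: int
    truth: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def sequence(self) -> str:
        return _decode(self.codes)

    def truth_proportions(self) -> dict[str, float]:
        return dict(zip(self.truth["family"], self.truth["proportion"]))

    def size_2C_pg(self) -> float:
        """Flow-cytometry style 2C value implied by the truth (1 pg = 0.978 Gbp)."""
        return 2 * self.c1_length / 0.978e9


# ---------------------------------------------------------------- construction


def _mutate(codes: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. substitutions at the given per-site rate (no indels)."""
    if divergence <= 0:
        return codes.copy()
    out = codes.copy()
    hits = np.nonzero(rng.random(out.shape[0]) < divergence)[0]
    if hits.size:
        # replace with one of the three other bases
        out[hits] = (out[hits] + rng.integers(1, 4, hits.size)) % 4
    return out


def _assemble(
    label: str,
    copies_pieces: list[tuple[str, np.ndarray]],
    bg_pieces: list[tuple[str, np.ndarray]],
    rng: np.random.Generator,
    c1_length: int,
    expected_copies: dict[str, int],
    copies: dict[str, int],
) -> Genome:
    """Interleave shuffled repeat copies with unique background spacers.

    Every copy is flanked by background so that reads never span a direct
    junction between two different repeat copies (tandem adjacency and
    nesting of distinct elements are not modeled in v1); spacers of at
    least one read length make family clusters structurally separable.
    """
    order = rng.permutation(len(copies_pieces))
    segs: list[tuple[str, np.ndarray]] = []
    bi = 0
    for ci in order:
        if bi < len(bg_pieces):
            segs.append(bg_pieces[bi])
            bi += 1
        segs.append(copies_pieces[ci])
    segs.extend(bg_pieces[bi:])
    codes = np.concatenate([s[1] for s in segs]) if segs else np.empty(0, np.uint8)
    bounds = np.cumsum([s[1].shape[0] for s in segs])
    labels = [s[0] for s in segs]

    base_counts: dict[str, int] = {}
    for lab, arr in segs:
        base_counts[lab] = base_counts.get(lab, 0) + arr.shape[0]
    total = int(codes.shape[0])
    truth = pd.DataFrame(
        {
            "family": list(base_counts),
            "copies": [copies.get(f, 0) for f in base_counts],
            "expected_copies": [expected_copies.get(f, 0) for f in base_counts],
            "bases": [base_counts[f] for f in base_counts],
        }
    )
    truth["proportion"] = truth["bases"] / total
    truth = truth.sort_values("family", ignore_index=True)
    return Genome(label, codes, bounds, labels, c1_length, truth)


def _background_pieces(
    length: int, n_chunks: int, rng: np.random.Generator, min_len: int = 150
) -> list[tuple[str, np.ndarray]]:
    if length <= 0:
        return []
    n_chunks = max(1, min(n_chunks, length))
    min_len = min(min_len, length // n_chunks)
    slack = length - min_len * n_chunks
    extra = np.zeros(n_chunks, np.int64)
    if slack > 0 and n_chunks > 1:
        cuts = np.sort(rng.integers(0, slack + 1, n_chunks - 1))
        extra = np.diff(np.concatenate(([0], cuts, [slack])))
    elif slack > 0:
        extra[0] = slack
    seq = rng.integers(0, 4, length).astype(np.uint8)
    pieces = []
    prev = 0
    for c in min_len + extra:
        pieces.append((BACKGROUND, seq[prev : prev + int(c)]))
        prev += int(c)
    return pieces


def build_parental_genome(spec: GenomeSpec, seed: int) -> Genome:
    """Materialise a monoploid parental genome from its spec.

    Each repeat copy is the family consensus mutated at the component's
    divergence; copies and background chunks are shuffled into a single
    sequence.  Truth-table base counts sum exactly to the genome length.
    """
    if spec.total_length() <= 0 or (not spec.components and spec.background_length == 0):
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    pieces: list[tuple[str, np.ndarray]] = []
    copies: dict[str, int] = {}
    for comp in spec.components:
        cons = encode(comp.family.consensus)
        copies[comp.family.name] = comp.copy_number
        for _ in range(comp.copy_number):
            pieces.append((comp.family.name, _mutate(cons, comp.divergence, rng)))
    n_copies = sum(copies.values())
    bg = _background_pieces(spec.background_length, n_copies + 1, rng)
    total = spec.total_length()
    return _assemble(spec.label, pieces, bg, rng, total, dict(copies), copies)


def build_hybrid_genome(h: HybridSpec, seed: int) -> Genome:
    """Materialise a hybrid genome: the dosage-weighted parental complements.

    The sequence is the full somatic (2C) complement: ``d_A`` monoploid
    copies of parent A's component set plus ``d_B`` of parent B's.  Each
    burst ``(family, a)`` multiplies that family's copy number by ``a``
    per parental origin, rounded to nearest with ties up.  The truth table
    records both expected (dosage-only) and realised (burst) copy numbers.
    """
    d_a, d_b = h.dosage
    rng = np.random.default_rng(seed)
    burst = dict(h.bursts)
    pieces: list[tuple[str, np.ndarray]] = []
    copies: dict[str, int] = {}
    expected: dict[str, int] = {}
    for dose, spec in ((d_a, h.parentA_spec), (d_b, h.parentB_spec)):
        for comp in spec.components:
            name = comp.family.name
            n_exp = dose * comp.copy_number
            n_real = round_half_up(n_exp * burst.get(name, 1.0))
            expected[name] = expected.get(name, 0) + n_exp
            copies[name] = copies.get(name, 0) + n_real
            cons = encode(comp.family.consensus)
            for _ in range(n_real):
                pieces.append((name, _mutate(cons, comp.divergence, rng)))
    bg_len = d_a * h.parentA_spec.background_length + d_b * h.parentB_spec.background_length
    bg = _background_pieces(bg_len, sum(copies.values()) + 1, rng)
    total = bg_len + sum(arr.shape[0] for _, arr in pieces)
    # 1C is half of the somatic complement, burst included (what flow
    # cytometry would measure on the hybrid).
    c1 = (total + 1) // 2
    return _assemble(h.label, pieces, bg, rng, c1, expected, copies)


# ------------------------------------------------------------------ sequencing


def simulate_reads(genome: Genome, p: ReadSimParams, seed: int, sample: str = "") -> ReadSet:
    """Draw paired-end reads uniformly from a genome.

    The number of pairs is ``round(coverage * len(genome) / (2 * read_length))``.
    Mate 2 is the reverse complement of the opposite fragment end.  Each
    pair is truth-tagged with the family owning the largest share of its
    fragment.  Substitution errors get the low quality score, correct
    bases the high one, so the quality filter has something to act on.
    Deterministic for a fixed seed.
    """
    L = genome.codes.shape[0]
    rl = p.read_length
    if L <= p.insert_mean:
        raise ValueError("genome shorter than one insert")
    n_pairs = round(p.coverage * L / (2 * rl))
    rng = np.random.default_rng(seed)
    sample = sample or genome.label

    inserts = np.clip(
        np.rint(rng.normal(p.insert_mean, p.insert_sd, n_pairs)).astype(np.int64),
        rl,
        L - 1,
    )
    starts = (rng.random(n_pairs) * (L - inserts)).astype(np.int64)
    qc = chr(p.quality_correct + 33)
    qe = chr(p.quality_error + 33)

    bounds = genome.seg_bounds
    labels = genome.seg_labels
    pairs = []
    for idx in range(n_pairs):
        s = int(starts[idx])
        ins = int(inserts[idx])
        frag = genome.codes[s : s + ins]
        m1 = frag[:rl].copy()
        m2 = revcomp_codes(frag[ins - rl : ins])
        seqs = []
        quals = []
        for m in (m1, m2):
            err = np.nonzero(rng.random(rl) < p.error_rate)[0]
            if err.size:
                m[err] = (m[err] + rng.integers(1, 4, err.size)) % 4
            q = np.full(rl, ord(qc), np.uint8)
            q[err] = ord(qe)
            seqs.append(_decode(m))
            quals.append(q.tobytes().decode("ascii"))
        # majority-overlap truth tag for the fragment
        lo = int(np.searchsorted(bounds, s, side="right"))
        hi = int(np.searchsorted(bounds, s + ins - 1, side="right"))
        if lo == hi:
            tag = labels[lo]
        else:
            best: dict[str, int] = {}
            pos = s
            for k in range(lo, hi + 1):
                end = int(bounds[k]) if k < len(labels) else L
                ov = min(end, s + ins) - pos
                best[labels[k]] = best.get(labels[k], 0) + ov
                pos = end
            tag = max(best.items(), key=lambda kv: (kv[1], kv[0]))[0]
        pairs.append(
            ReadPair(
                id=f"{sample}.{idx}",
                seq1=seqs[0],
                qual1=quals[0],
                seq2=seqs[1],
                qual2=quals[1],
                sample=sample,
                truth=tag,
            )
        )
    return ReadSet(pairs)


def reads_for_c1_coverage(genome: Genome, c1_coverage: float) -> float:
    """Sequence-level coverage to pass so a dataset covers 1C at the target.

    For a parental monoploid build this is the target itself; for a hybrid
    (sequence = 2C) it is half, since reads are drawn over the whole
    complement but coverage is accounted per 1C.
    """
    return c1_coverage * genome.c1_length / genome.codes.shape[0]


# ------------------------------------------------------------- demo repeatomes


def random_consensus(length: int, rng: np.random.Generator) -> str:
    return _decode(rng.integers(0, 4, length).astype(np.uint8))


def demo_families(seed: int = 20) -> dict[str, RepeatFamily]:
    """Repeat families for the desk-scale demo genomes.

    Three medium/high-abundance LTR-retrotransposon-like families carry the
    comparative analyses (at 0.066x coverage only such families are counted
    precisely enough for dosage tests); tandem satellites, rDNA and a
    pararetrovirus exercise annotation, tandem detection and read screening.
    Each dispersed family carries a central "domain" segment used as its
    protein-domain stand-in by the annotator.
    """
    rng = np.random.default_rng(seed)
    fams: dict[str, RepeatFamily] = {}

    def dispersed(name, lineage, length, dom_len):
        s = (length - dom_len) // 2
        fams[name] = RepeatFamily(
            name=name,
            lineage=lineage,
            consensus=random_consensus(length, rng),
            domain_segments=((s, s + dom_len, lineage),),
        )

    dispersed("tekay_like", "Ty3/Gypsy:chromovirus/Tekay", 8000, 900)
    dispersed("sire_like", "Ty1/Copia:SIRE", 6000, 800)
    dispersed("angela_like", "Ty1/Copia:Angela", 5000, 700)
    dispersed("athila_like", "Ty3/Gypsy:non-chromovirus/OTA/Athila", 4000, 600)
    dispersed("cacta_like", "DNA-transposon:EnSpm_CACTA", 3000, 500)
    dispersed("prv_like", "pararetrovirus", 2000, 400)
    for name, monomer in (("sat46", 46), ("sat126", 126), ("sat172", 172)):
        unit = random_consensus(monomer, rng)
        n_units = max(3, 500 // monomer)
        fams[name] = RepeatFamily(
            name=name,
            lineage=f"satellite:{name}",
            consensus=unit * n_units,
            monomer_length=monomer,
        )
    rdna45 = random_consensus(1500, rng)
    fams["rdna45"] = RepeatFamily(
        "rdna45", "45S-rDNA", rdna45, domain_segments=((100, 1400, "45S-rDNA"),)
    )
    rdna5 = random_consensus(500, rng)
    fams["rdna5"] = RepeatFamily(
        "rdna5", "5S-rDNA", rdna5, domain_segments=((50, 450, "5S-rDNA"),)
    )
    return fams


def comparative_parent_specs(
    genome_length: int = 5_000_000,
    divergence: float = 0.02,
    seed: int = 20,
) -> tuple[GenomeSpec, GenomeSpec]:
    """The two parental genomes used by the comparative (dosage) analyses.

    Both parents share the same three dominant families at moderately
    different abundances (A: 34/20/20 %, B: 28/26/15 % of the monoploid
    genome), i.e. ~70 % repetitive like the genomes the method is built
    for; the per-family differences give desk-scale runs enough signal
    for direction statistics (parent distances, tier ordering) to be
    informative at 0.066x coverage.  The long tail of rare families is
    deliberately absent here: at that coverage their read counts are
    binomial-noise-dominated and carry no information about dosage (the
    well-known "widening tail" of low-coverage comparative clustering).
    """
    fams = demo_families(seed)
    abund_a = {"tekay_like": 0.34, "sire_like": 0.20, "angela_like": 0.20}
    abund_b = {"tekay_like": 0.28, "sire_like": 0.26, "angela_like": 0.15}

    def spec(label, abund):
        comps = []
        used = 0
        for name, frac in abund.items():
            fam = fams[name]
            n = round(frac * genome_length / len(fam.consensus))
            comps.append(GenomeComponent(fam, n, divergence))
            used += n * len(fam.consensus)
        return GenomeSpec(label, tuple(comps), background_length=genome_length - used)

    return spec("parentA", abund_a), spec("parentB", abund_b)


def full_parent_specs(
    genome_length: int = 1_000_000,
    divergence: float = 0.02,
    seed: int = 20,
) -> tuple[GenomeSpec, GenomeSpec]:
    """Richer parental genomes for individual clustering and annotation.

    Adds the low-abundance component classes (satellites, rDNA,
    pararetrovirus, DNA transposon) on top of the dominant families, at
    proportions patterned on a highly repetitive plant genome.
    """
    fams = demo_families(seed)
    abund_a = {
        "tekay_like": 0.26,
        "sire_like": 0.17,
        "angela_like": 0.05,
        "athila_like": 0.02,
        "cacta_like": 0.006,
        "prv_like": 0.002,
        "sat46": 0.004,
        "sat126": 0.003,
        "rdna45": 0.006,
        "rdna5": 0.001,
    }
    abund_b = {
        "tekay_like": 0.28,
        "sire_like": 0.14,
        "angela_like": 0.055,
        "athila_like": 0.017,
        "cacta_like": 0.007,
        "sat172": 0.004,
        "sat126": 0.002,
        "rdna45": 0.007,
        "rdna5": 0.001,
    }

    def spec(label, abund):
        comps = []
        used = 0
        for name, frac in abund.items():
            fam = fams[name]
            div = 0.01 if fam.monomer_length else divergence
            n = max(1, round(frac * genome_length / len(fam.consensus)))
            comps.append(GenomeComponent(fam, n, div))
            used += n * len(fam.consensus)
        return GenomeSpec(label, tuple(comps), background_length=genome_length - used)

    return spec("parentA", abund_a), spec("parentB", abund_b)


def organelle_reference(length: int = 30_000, seed: int = 77) -> str:
    """A synthetic plastid-like reference used by the organelle filter demo."""
    return random_consensus(length, np.random.default_rng(seed))
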