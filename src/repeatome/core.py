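"""Core containers: mate pairs of reads and sets of them.

A :class:`ReadPair` is the universal currency of the pipeline: two 150 bp
mates with Phred+33 quality strings, a sample label, and (for simulated
data) a truth tag naming the repeat family the fragment was drawn from.
:class:`ReadSet` is an ordered collection of pairs with FASTQ round-trip
support via Biopython.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BACKGROUND = "background"


@dataclass(frozen=True)
class ReadPair:
    """One sequenced mate pair.

    ``id`` excludes the ``/1`` ``/2`` mate suffix.  ``truth`` is the name
    of the originating repeat family (or ``"background"``) when known,
    ``None`` for real data.
    """

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    sample: str = ""
    truth: str | None = None

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1):
            raise ValueError(f"read {self.id}/1: sequence/quality length mismatch")
        if len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}/2: sequence/quality length mismatch")

    def phred1(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual1]

    def phred2(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual2]


class ReadSet:
    """Ordered collection of :class:`ReadPair` objects with unique ids."""

    def __init__(self, pairs: Iterable[ReadPair] = ()):  # noqa: D107
        self.pairs: list[ReadPair] = list(pairs)
        ids = [p.id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate read ids in ReadSet")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[ReadPair]:
        return iter(self.pairs)

    def __getitem__(self, i):
        return self.pairs[i]

    @property
    def n_reads(self) -> int:
        """Number of individual reads (2 per pair)."""
        return 2 * len(self.pairs)

    def with_sample(self, sample: str) -> "ReadSet":
        return ReadSet(replace(p, sample=sample) for p in self.pairs)

    def with_id_prefix(self, prefix: str) -> "ReadSet":
        return ReadSet(replace(p, id=f"{prefix}{p.id}") for p in self.pairs)

    def truth_proportions(self) -> dict[str, float]:
        """Fraction of reads per truth tag (mates counted separately)."""
        counts: dict[str, int] = {}
        for p in self.pairs:
            tag = p.truth if p.truth is not None else "unknown"
            counts[tag] = counts.get(tag, 0) + 2
        total = self.n_reads
        return {k: v / total for k, v in counts.items()}

    # ---------------------------------------------------------------- IO

    def to_fastq(self, path1: str | Path, path2: str | Path) -> None:
        """Write mates to two FASTQ files (``<id>/1`` and ``<id>/2``)."""

        def records(mate: int):
            for p in self.pairs:
                seq = p.seq1 if mate == 1 else p.seq2
                qual = p.qual1 if mate == 1 else p.qual2
                desc = []
                if p.sample:
                    desc.append(f"sample={p.sample}")
                if p.truth is not None:
                    desc.append(f"truth={p.truth}")
                rec = SeqRecord(
                    Seq(seq),
                    id=f"{p.id}/{mate}",
                    description=" ".join(desc),
                )
                rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
                yield rec

        SeqIO.write(records(1), str(path1), "fastq")
        SeqIO.write(records(2), str(path2), "fastq")

    @classmethod
    def from_fastq(cls, path1: str | Path, path2: str | Path) -> "ReadSet":
        pairs = []
        it1 = SeqIO.parse(str(path1), "fastq")
        it2 = SeqIO.parse(str(path2), "fastq")
        for r1, r2 in itertools.zip_longest(it1, it2):
            if r1 is None or r2 is None:
                raise ValueError("FASTQ mate files have unequal numbers of reads")
            id1 = r1.id.rsplit("/", 1)[0]
            id2 = r2.id.rsplit("/", 1)[0]
            if id1 != id2:
                raise ValueError(f"mate id mismatch: {r1.id} vs {r2.id}")
            tags = dict(
                t.split("=", 1)
                for t in r1.description.split()[1:]
                if "=" in t
            )
            pairs.append(
                ReadPair(
                    id=id1,
                    seq1=str(r1.seq),
                    qual1="".join(
                        chr(q + 33) for q in r1.letter_annotations["phred_quality"]
                    ),
                    seq2=str(r2.seq),
                    qual2="".join(
                        chr(q + 33) for q in r2.letter_annotations["phred_quality"]
                    ),
                    sample=tags.get("sample", ""),
                    truth=tags.get("truth"),
                )
            )
        return cls(pairs)


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    """Write a name -> sequence mapping as FASTA."""
    SeqIO.write(
        (SeqRecord(Seq(s), id=n, description="") for n, s in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
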