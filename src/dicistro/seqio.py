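"""Sequence I/O, coordinate conventions and composition utilities.

Conventions shared by every module in the package:

* Coordinates are **1-based inclusive**, as in GenBank feature tables.
  Any half-open arithmetic is internal and converted at the API boundary.
* Sequences are canonicalized to the DNA alphabet (``U`` -> ``T``, upper
  case).  Display layers may render ``U`` for RNA genomes; analysis always
  sees the canonical form.
* IUPAC ambiguity codes are tolerated in stored sequences but are treated
  as mismatches by downstream comparison operations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")


def canonicalize(seq: str) -> str:
    """Upper-case, strip whitespace, and map the RNA alphabet onto DNA."""
    return "".join(seq.split()).upper().replace("U", "T")


@dataclass(frozen=True)
class GenomeRecord:
    """A single-molecule nucleotide sequence with 1-based coordinates.

    The constructor canonicalizes the sequence; an illegal character (outside
    the IUPAC DNA alphabet) raises ``ValueError`` naming the record and the
    1-based offending position.
    """

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", canonicalize(self.seq))
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for i, base in enumerate(self.seq, start=1):
            if base not in IUPAC_DNA:
                raise ValueError(
                    f"record {self.id!r}: illegal character {base!r} at position {i}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.seq)


@dataclass(frozen=True)
class Region:
    """1-based inclusive interval, optionally carrying a codon-frame anchor."""

    start: int
    end: int
    frame_anchor: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def phase(self) -> Optional[int]:
        if self.frame_anchor is None:
            return None
        return (self.frame_anchor - self.start) % 3

    def check_within(self, record: GenomeRecord) -> None:
        if self.end > record.length:
            raise ValueError(
                f"region {self.start}..{self.end} outside record "
                f"{record.id!r} of length {record.length}"
            )

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


def subseq(record: GenomeRecord, region: Region) -> str:
    region.check_within(record)
    return record.seq[region.start - 1 : region.end]


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into canonicalized :class:`GenomeRecord` s."""
    records = [
        GenomeRecord(id=rec.id, seq=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA (60-column lines)."""
    seqrecs = [
        SeqRecord(Seq(rec.seq), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def gc_content(record: GenomeRecord, region: Optional[Region] = None) -> float:
    """(#G + #C) / (#A + #C + #G + #T) within ``region``.

    Ambiguity codes are excluded from numerator and denominator alike.
    """
    region = region or Region(1, record.length)
    s = subseq(record, region)
    unamb = [b for b in s if b in UNAMBIGUOUS]
    if not unamb:
        raise ValueError("region contains no unambiguous bases")
    gc = sum(1 for b in unamb if b in "GC")
    return gc / len(unamb)


def count_motif(record: GenomeRecord, region: Region, motif: str) -> int:
    """Count (possibly overlapping) occurrences of ``motif`` fully inside ``region``."""
    motif = canonicalize(motif)
    if not motif:
        raise ValueError("empty motif")
    s = subseq(record, region)
    count = 0
    start = 0
    while True:
        idx = s.find(motif, start)
        if idx == -1:
            return count
        count += 1
        start = idx + 1


# ---------------------------------------------------------------------------
# Plain-text writers shared by the pipeline
# ---------------------------------------------------------------------------


def write_tsv(
    path: str | Path,
    rows: Iterable[Sequence],
    columns: Sequence[str],
    comments: Sequence[str] = (),
) -> None:
    with open(path, "w", newline="") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        writer.writerows(rows)


@dataclass(frozen=True)
class Gff3Row:
    """One GFF3 feature line (1-based inclusive coordinates, forward strand)."""

    seqid: str
    type: str
    start: int
    end: int
    score: Optional[float] = None
    phase: Optional[int] = None
    attributes: Mapping[str, str] = field(default_factory=dict)
    source: str = "dicistro"
    strand: str = "+"

    def format(self) -> str:
        score = "." if self.score is None else f"{self.score:g}"
        phase = "." if self.phase is None else str(self.phase)
        attrs = (
            ";".join(f"{k}={v}" for k, v in self.attributes.items())
            if self.attributes
            else "."
        )
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.type,
                str(self.start),
                str(self.end),
                score,
                self.strand,
                phase,
                attrs,
            ]
        )


def write_gff3(path: str | Path, rows: Iterable[Gff3Row], header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for row in rows:
            fh.write(row.format() + "\n")


def read_gff3(path: str | Path) -> list[Gff3Row]:
    """Minimal reader for files produced by :func:`write_gff3` (round-trip checks)."""
    rows: list[Gff3Row] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            seqid, source, ftype, start, end, score, strand, phase, attrs = line.split("\t")
            attributes = {}
            if attrs != ".":
                for item in attrs.split(";"):
                    k, _, v = item.partition("=")
                    attributes[k] = v
            rows.append(
                Gff3Row(
                    seqid=seqid,
                    source=source,
                    type=ftype,
                    start=int(start),
                    end=int(end),
                    score=None if score == "." else float(score),
                    strand=strand,
                    phase=None if phase == "." else int(phase),
                    attributes=attributes,
                )
            )
    return rows
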