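"""FASTA/GFF3 I/O, coordinate arithmetic and translation.

All coordinates are 0-based half-open internally. GFF3 is written 1-based
inclusive per the standard; minus-strand features are stored on the forward
strand with a strand flag, GFF3-style. Sequences are upper-cased on load and
restricted to the {A, C, G, T, N} alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = frozenset("ACGTN")
_VALID_SEQ_RE = re.compile(r"^[ACGTN]*$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# codon -> amino acid, stops rendered '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
START_CODON = "ATG"


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (duplicate ids, illegal characters)."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not _VALID_SEQ_RE.match(self.seq):
            bad = sorted(set(self.seq) - NUCLEOTIDES)
            raise FastaFormatError(
                f"sequence {self.id!r} contains illegal characters {bad!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a contig, with a strand flag."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def extract(self, genome: GenomeSequence) -> str:
        """Strand-aware subsequence: minus-strand features are reverse-complemented."""
        if self.end > genome.length:
            raise ValueError(
                f"interval end {self.end} beyond contig {genome.id} "
                f"length {genome.length}"
            )
        sub = genome.seq[self.start : self.end]
        return reverse_complement(sub) if self.strand == "-" else sub

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records, upper-cased, order preserved."""
    path = Path(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(GenomeSequence(id=rec.id, seq=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[GenomeSequence | tuple[str, str]],
                path: str | Path, width: int = 60) -> None:
    seqrecs = []
    for rec in records:
        if isinstance(rec, GenomeSequence):
            seqrecs.append(SeqRecord(Seq(rec.seq), id=rec.id, description=""))
        else:
            rec_id, seq = rec
            seqrecs.append(SeqRecord(Seq(seq), id=rec_id, description=""))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecs)


def reverse_complement(seq: str) -> str:
    if not _VALID_SEQ_RE.match(seq):
        bad = sorted(set(seq) - NUCLEOTIDES)
        raise ValueError(f"illegal characters in sequence: {bad!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 0) -> str:
    """Translate in the standard genetic code.

    Stops render as '*'; any codon containing N translates to 'X';
    trailing 1-2 nt are dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    coding = nt[frame:]
    aa = []
    for i in range(0, len(coding) - 2, 3):
        codon = coding[i : i + 3]
        aa.append(CODON_TABLE.get(codon, "X"))
    return "".join(aa)


# --- GFF3 ------------------------------------------------------------------

@dataclass(frozen=True)
class Gff3Feature:
    interval: GenomicInterval
    type: str
    source: str = "erv-env-miner"
    score: str = "."
    attributes: str = "."


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            iv = feat.interval
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        feat.source,
                        feat.type,
                        str(iv.start + 1),
                        str(iv.end),
                        feat.score,
                        iv.strand,
                        ".",
                        feat.attributes,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    """Parse a GFF3 file back to features (coordinates converted to 0-based)."""
    feats: list[Gff3Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, source, ftype, start, end, score, strand, _phase, attrs = cols
            feats.append(
                Gff3Feature(
                    interval=GenomicInterval(
                        contig=contig,
                        start=int(start) - 1,
                        end=int(end),
                        strand=strand,
                    ),
                    type=ftype,
                    source=source,
                    score=score,
                    attributes=attrs,
                )
            )
    return feats
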