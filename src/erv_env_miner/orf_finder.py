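"""Six-frame ORF enumeration.

Two modes, mirroring how proviral maps are usually drawn: ``start_to_stop``
ORFs run from the 5'-most ATG of a stop-delimited segment to the stop codon
(the screen used for candidate envelope genes, at a minimum of 400 codons),
and ``stop_to_stop`` ORFs are the full stop-delimited segments (used for
provirus structure maps, filled above 300 nt).

Codons containing N translate to 'X' and never terminate an ORF; ORFs with
more than 5% 'X' are flagged low-confidence rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequence_io import GenomeSequence, GenomicInterval, reverse_complement, translate

START_TO_STOP = "start_to_stop"
STOP_TO_STOP = "stop_to_stop"

X_FRACTION_FLAG = 0.05


@dataclass(frozen=True)
class OrfRecord:
    interval: GenomicInterval
    frame: int
    mode: str
    nt_seq: str
    aa_seq: str
    low_confidence: bool = field(default=False, compare=False)

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)

    @property
    def has_terminal_stop(self) -> bool:
        return self.interval.length == 3 * self.aa_len + 3

    @property
    def id(self) -> str:
        iv = self.interval
        return f"{iv.contig}:{iv.start}-{iv.end}({iv.strand})"


def _segments(prot: str):
    """Yield (aa_start, aa_end, has_stop) for each stop-delimited segment."""
    start = 0
    for i, aa in enumerate(prot):
        if aa == "*":
            yield start, i, True
            start = i + 1
    if start < len(prot):
        yield start, len(prot), False


def _scan_strand(
    seq: str,
    contig: str,
    contig_len: int,
    strand: str,
    min_codons: int,
    mode: str,
    strict_gt: bool,
    all_starts: bool,
) -> list[OrfRecord]:
    records: list[OrfRecord] = []
    for frame in (0, 1, 2):
        prot = translate(seq, frame)
        for seg_start, seg_end, has_stop in _segments(prot):
            if mode == STOP_TO_STOP:
                candidates = [seg_start] if seg_end > seg_start else []
            elif all_starts:
                candidates = [
                    p for p in range(seg_start, seg_end) if prot[p] == "M"
                ]
            else:
                mi = prot.find("M", seg_start, seg_end)
                candidates = [mi] if mi >= 0 else []
            for orf_start in candidates:
                aa_seq = prot[orf_start:seg_end]
                aa_len = len(aa_seq)
                if aa_len < min_codons or (strict_gt and aa_len == min_codons):
                    continue
                nt_start = frame + 3 * orf_start
                nt_end = frame + 3 * seg_end + (3 if has_stop else 0)
                if strand == "+":
                    fwd_start, fwd_end = nt_start, nt_end
                else:
                    fwd_start, fwd_end = contig_len - nt_end, contig_len - nt_start
                x_frac = aa_seq.count("X") / aa_len
                records.append(
                    OrfRecord(
                        interval=GenomicInterval(contig, fwd_start, fwd_end, strand),
                        frame=frame,
                        mode=mode,
                        nt_seq=seq[nt_start:nt_end],
                        aa_seq=aa_seq,
                        low_confidence=x_frac > X_FRACTION_FLAG,
                    )
                )
    return records


def find_orfs(
    seq: GenomeSequence | str,
    min_codons: int = 400,
    mode: str = START_TO_STOP,
    both_strands: bool = True,
    strict_gt: bool = False,
    all_starts: bool = False,
) -> list[OrfRecord]:
    """Enumerate ORFs of at least ``min_codons`` codons.

    ``strict_gt`` switches the boundary to strictly more than ``min_codons``
    codons. ``all_starts`` reports one ORF per internal ATG instead of only
    the 5'-most ATG of each stop-delimited segment.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    if mode not in (START_TO_STOP, STOP_TO_STOP):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(seq, str):
        seq = GenomeSequence(id="seq", seq=seq.upper())
    records = _scan_strand(
        seq.seq, seq.id, seq.length, "+", min_codons, mode, strict_gt, all_starts
    )
    if both_strands:
        records += _scan_strand(
            reverse_complement(seq.seq),
            seq.id,
            seq.length,
            "-",
            min_codons,
            mode,
            strict_gt,
            all_starts,
        )
    records.sort(key=lambda r: (r.interval.contig, r.interval.start, r.interval.end,
                                r.interval.strand, r.mode))
    return records


def annotate_provirus_orfs(provirus_seq: str, min_nt: int = 300) -> list[OrfRecord]:
    """Plus-strand ORFs longer than ``min_nt`` nt, in both modes, for structure maps."""
    out: list[OrfRecord] = []
    for mode in (STOP_TO_STOP, START_TO_STOP):
        for rec in find_orfs(
            provirus_seq, min_codons=1, mode=mode, both_strands=False
        ):
            if rec.interval.length > min_nt:
                out.append(rec)
    return out
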