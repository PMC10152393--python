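"""Direct-repeat (LTR) detection around candidate envelope ORFs.

A provirus is delimited by its two LTRs, which were identical at
integration. Around each candidate env ORF a +/-10-kbp window is cut out
and searched for long direct repeats: exact k-mer seeds shared between two
window positions are chained on nearby diagonals, chains are extended
outward with an X-drop scan, and the two repeat copies are then aligned
globally to score the pair and measure percent identity. The best pair
that brackets the env ORF delimits the provirus.

No target-site-duplication or PBS/PPT evidence is used: bracketing plus
repeat identity is the whole call, since only LTR coordinates and identity
feed the downstream dating.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .divergence_dating import align_global, ltr_identity
from .orf_finder import OrfRecord
from .sequence_io import GenomeSequence, GenomicInterval

DEFAULT_FLANK = 10_000
DEFAULT_MIN_LTR = 100
DEFAULT_MAX_LTR = 3_000
DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_SEED_K = 12
DEFAULT_BAND = 32

_XDROP = 20
_MAX_SEED_GAP = 500
_MAX_KMER_HITS = 50


@dataclass(frozen=True)
class LtrPair:
    left: GenomicInterval
    right: GenomicInterval
    identity_pct: float
    score: float

    def __post_init__(self) -> None:
        if self.left.end > self.right.start:
            raise ValueError("left LTR must precede right LTR")


@dataclass(frozen=True)
class ProvirusCall:
    env_orf: OrfRecord
    ltr_pair: LtrPair | None
    internal_orfs: list = field(default_factory=list)

    @property
    def provirus_interval(self) -> GenomicInterval | None:
        if self.ltr_pair is None:
            return None
        return GenomicInterval(
            self.ltr_pair.left.contig,
            self.ltr_pair.left.start,
            self.ltr_pair.right.end,
            self.env_orf.interval.strand,
        )


def extract_window(
    genome: GenomeSequence, env_orf: OrfRecord, flank: int = DEFAULT_FLANK
) -> tuple[str, int]:
    """Window of ``flank`` bp either side of the ORF, clipped to the contig.

    Returns (window sequence, genomic offset of the window start); window
    coordinate w maps back to genome coordinate w + offset.
    """
    start = max(0, env_orf.interval.start - flank)
    end = min(genome.length, env_orf.interval.end + flank)
    return genome.seq[start:end], start


def _xdrop_extend(window: str, i: int, j: int, direction: int) -> int:
    """Ungapped +1/-2 extension from (i, j); returns offset of the best end.

    ``direction`` +1 extends right from the given first positions, -1 left.
    The returned value is the number of columns included (argmax of the
    running score before the score drops _XDROP below its maximum). The
    -2 mismatch penalty keeps chance matches in the flanking sequence from
    dragging the boundary outward while still absorbing the sparse
    mismatches of a diverged repeat.
    """
    n = len(window)
    score = 0
    best_score = 0
    best_t = 0
    t = 0
    while True:
        a = i + direction * t
        b = j + direction * t
        if a < 0 or b < 0 or a >= n or b >= n:
            break
        if direction > 0 and b <= a:
            break
        score += 1 if window[a] == window[b] else -2
        t += 1
        if score > best_score:
            best_score, best_t = score, t
        if score < best_score - _XDROP:
            break
    return best_t


def find_direct_repeats(
    window: str,
    min_ltr_len: int = DEFAULT_MIN_LTR,
    max_ltr_len: int = DEFAULT_MAX_LTR,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = DEFAULT_SEED_K,
    band: int = DEFAULT_BAND,
    contig: str = "window",
    offset: int = 0,
) -> list[LtrPair]:
    """Call candidate direct-repeat pairs in a window, best score first.

    Exact k-mer seed pairs are grouped on diagonal bands (diagonal
    difference <= ``band``), chained along the window, extended with an
    X-drop scan, and the resulting repeat copies aligned to obtain identity
    and the ranking score. Pairs violating the length or identity bounds
    are dropped. Coordinates are reported on ``contig`` shifted by
    ``offset`` (pass the window's genomic offset to get genome coordinates).
    """
    n = len(window)
    if n < 2 * min_ltr_len:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        kmer = window[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    # seed pairs grouped by diagonal (j - i)
    by_diag: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for positions in index.values():
        if len(positions) < 2 or len(positions) > _MAX_KMER_HITS:
            continue
        for ai, i in enumerate(positions):
            for j in positions[ai + 1 :]:
                if j - i >= min_ltr_len:
                    by_diag[j - i].append((i, j))
    # merge nearby diagonals into bands, then chain seeds along the window
    chains: list[list[tuple[int, int]]] = []
    current_band: list[tuple[int, int, int]] = []  # (diag, i, j)
    for diag in sorted(by_diag):
        if current_band and diag - current_band[-1][0] > band:
            chains.extend(_chain_band(current_band, k))
            current_band = []
        current_band.extend((diag, i, j) for i, j in by_diag[diag])
    if current_band:
        chains.extend(_chain_band(current_band, k))

    pairs: list[LtrPair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for chain in chains:
        i0, j0 = chain[0]
        i1, j1 = chain[-1]
        left_ext = _xdrop_extend(window, i0 - 1, j0 - 1, -1)
        right_ext = _xdrop_extend(window, i1 + k, j1 + k, +1)
        ls, le = i0 - left_ext, i1 + k + right_ext
        rs, re = j0 - left_ext, j1 + k + right_ext
        key = (ls // 8, le // 8, rs // 8, re // 8)
        if key in seen:
            continue
        seen.add(key)
        if not (min_ltr_len <= le - ls <= max_ltr_len):
            continue
        if not (min_ltr_len <= re - rs <= max_ltr_len):
            continue
        if le > rs:
            continue
        aln = align_global(window[ls:le], window[rs:re])
        ident = ltr_identity(aln)
        if ident < min_identity:
            continue
        score = (
            aln.n_ungapped_columns
            - 2 * aln.n_mismatches
            - 2 * (aln.n_columns - aln.n_ungapped_columns)
        )
        pairs.append(
            LtrPair(
                left=GenomicInterval(contig, offset + ls, offset + le),
                right=GenomicInterval(contig, offset + rs, offset + re),
                identity_pct=ident,
                score=float(score),
            )
        )
    pairs.sort(
        key=lambda p: (-p.score, -(p.left.length), p.left.start, p.right.start)
    )
    return _dedupe(pairs)


def _chain_band(seeds: list[tuple[int, int, int]], k: int):
    """Chain seeds of one diagonal band into runs along the window."""
    seeds = sorted(seeds, key=lambda s: s[1])
    chains: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    for _diag, i, j in seeds:
        if current and (
            i - current[-1][0] > _MAX_SEED_GAP or i < current[-1][0]
        ):
            chains.append(current)
            current = []
        if current and i == current[-1][0]:
            continue
        current.append((i, j))
    if current:
        chains.append(current)
    return chains


def _dedupe(pairs: list[LtrPair], slack: int = 20) -> list[LtrPair]:
    kept: list[LtrPair] = []
    for p in pairs:
        dup = any(
            abs(p.left.start - q.left.start) <= slack
            and abs(p.right.start - q.right.start) <= slack
            and abs(p.left.end - q.left.end) <= slack
            and abs(p.right.end - q.right.end) <= slack
            for q in kept
        )
        if not dup:
            kept.append(p)
    return kept


def call_provirus(
    env_orf: OrfRecord,
    candidates: list[LtrPair],
    internal_orfs: list | None = None,
) -> ProvirusCall:
    """Select the best LTR pair bracketing the env ORF.

    Bracketing (left LTR entirely 5' of the ORF, right LTR entirely 3')
    dominates score; ties break to the higher score, then the longer
    repeat, then the smaller left start. With no bracketing candidate the
    call carries no LTR pair (reported downstream with identity "-").
    """
    iv = env_orf.interval
    bracketing = [
        p
        for p in candidates
        if p.left.end <= iv.start and iv.end <= p.right.start
    ]
    bracketing.sort(key=lambda p: (-p.score, -(p.left.length), p.left.start))
    return ProvirusCall(
        env_orf=env_orf,
        ltr_pair=bracketing[0] if bracketing else None,
        internal_orfs=list(internal_orfs or []),
    )
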