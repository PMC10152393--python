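"""Envelope-protein feature annotation.

A retroviral Env precursor is cleaved by host furin at a minimal basic
R-x-[RK]-R site into the surface (SU, receptor binding) and transmembrane
(TM, fusion) subunits; the TM subunit is the conserved region used for
cross-family phylogeny. Envs of the RD114/D-type (RDR) interference group
additionally carry the SDGGGXXDXXR receptor-binding motif in SU, the
hallmark of ASCT1/ASCT2 receptor usage.

'X' (unknown) residues never satisfy a fixed motif position; motif
wildcards accept any residue except stops.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

DEFAULT_MIN_TAIL = 80

# R-x-[RK]-R: x is any residue except '*'; fixed positions reject 'X'
_FURIN_RE = re.compile(r"R[^*](?:R|K)R")
_RDR_RE = re.compile(r"SDGGG[^*][^*]D[^*][^*]R")


@dataclass(frozen=True)
class EnvAnnotation:
    furin_site: int | None  # index just after the motif's final R
    tm_region: str | None
    rdr_motif_positions: tuple[int, ...]


def find_furin_site(aa_seq: str, min_tail: int = DEFAULT_MIN_TAIL) -> int | None:
    """C-terminal-most furin motif leaving at least ``min_tail`` residues of TM.

    Returns the cleavage position (index just after the final R of the
    R-x-[RK]-R match), or None if no admissible match exists.
    """
    if not aa_seq:
        raise ValueError("empty sequence")
    best = None
    for m in _FURIN_RE.finditer(aa_seq):
        cleavage = m.start() + 4
        if len(aa_seq) - cleavage >= min_tail:
            best = cleavage
    return best


def extract_tm_region(aa_seq: str, furin_site: int) -> str:
    """Suffix downstream of the cleavage position — the TM subunit."""
    if furin_site is None:
        raise ValueError("furin site absent")
    tm = aa_seq[furin_site:]
    if not tm:
        raise ValueError("cleavage at the final residue leaves an empty TM")
    return tm


def find_rdr_motif(aa_seq: str) -> list[int]:
    """All start positions of the SDGGGxxDxxR receptor-binding motif."""
    if not aa_seq:
        raise ValueError("empty sequence")
    # overlapping matches via lookahead
    return [m.start() for m in re.finditer(r"(?=(SDGGG[^*][^*]D[^*][^*]R))", aa_seq)]


def annotate_env(aa_seq: str, min_tail: int = DEFAULT_MIN_TAIL) -> EnvAnnotation:
    site = find_furin_site(aa_seq, min_tail)
    return EnvAnnotation(
        furin_site=site,
        tm_region=extract_tm_region(aa_seq, site) if site is not None else None,
        rdr_motif_positions=tuple(find_rdr_motif(aa_seq)),
    )
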