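"""Envelope-ORF family clustering, alignment, consensus and tree helpers.

Multicopy ERV families are recently expanded, nearly identical insertions.
ORFs are grouped by single-linkage clustering on pairwise global-alignment
amino-acid identity (default threshold 80%), each multicopy family is
aligned progressively, sparse alignment columns (minor insertions private
to few members) are trimmed, and a per-column plurality consensus
represents the family. A neighbor-joining helper provides distance trees
for group structure.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .divergence_dating import align_global

DEFAULT_IDENTITY_THRESHOLD = 80.0
DEFAULT_MIN_RESIDUE_FRACTION = 0.6

_GAP_OPEN = -5.0
_GAP_EXTEND = -1.0

_ID_RE = re.compile(r"^(?P<contig>.+):(?P<start>\d+)-(?P<end>\d+)\([+-]\)$")


@dataclass
class EnvFamily:
    name: str
    members: list[str]
    consensus_nt: str | None = None
    consensus_aa: str | None = None

    @property
    def copy_number(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identical residues over ungapped columns of a global alignment."""
    aln = align_global(seq_a, seq_b)
    n = aln.n_ungapped_columns
    if n == 0:
        return 0.0
    return 100.0 * (n - aln.n_mismatches) / n


def _position_key(member_id: str) -> tuple:
    m = _ID_RE.match(member_id)
    if m:
        return (m.group("contig"), int(m.group("start")), int(m.group("end")))
    return (member_id, 0, 0)


def cluster_families(
    aa_seqs: dict[str, str] | list[tuple[str, str]],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    name_prefix: str = "env-F",
) -> list[EnvFamily]:
    """Single-linkage clustering of protein sequences into families.

    Sequence pairs at >= ``identity_threshold`` percent identity are linked;
    connected components form families. Families are named by descending
    copy number, then leftmost genomic position of their members (member
    ids of the form ``contig:start-end(strand)`` are understood), so the
    naming is invariant to input order.
    """
    items = list(aa_seqs.items()) if isinstance(aa_seqs, dict) else list(aa_seqs)
    if not items:
        raise ValueError("no sequences to cluster")
    items = sorted(items, key=lambda kv: _position_key(kv[0]))
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(items[i][1], items[j][1]) >= identity_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(items[i][0])
    ordered = sorted(
        groups.values(),
        key=lambda mem: (-len(mem), min(_position_key(m) for m in mem)),
    )
    return [
        EnvFamily(name=f"{name_prefix}{i + 1}", members=members)
        for i, members in enumerate(ordered)
    ]


# --- progressive multiple alignment ----------------------------------------

def _profile_columns(rows: list[str], alphabet: dict[str, int]) -> np.ndarray:
    """(n_columns, |alphabet|) residue counts; gaps contribute nothing."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, len(alphabet)))
    for row in rows:
        for c, ch in enumerate(row):
            idx = alphabet.get(ch)
            if idx is not None:
                counts[c, idx] += 1
    return counts


def _align_profiles(
    ids_a: list[str],
    rows_a: list[str],
    ids_b: list[str],
    rows_b: list[str],
) -> tuple[list[str], list[str]]:
    """Affine-gap profile-profile alignment (sum-of-pairs, +1/-1)."""
    alphabet = {ch: i for i, ch in enumerate(sorted({c for r in rows_a + rows_b for c in r if c != "-"}))}
    if not alphabet:
        alphabet = {"A": 0}
    fa = _profile_columns(rows_a, alphabet)
    fb = _profile_columns(rows_b, alphabet)
    na = fa.sum(axis=1)
    nb = fb.sum(axis=1)
    # mean pairwise residue score per column pair: +1 match, -1 mismatch
    denom = np.outer(na, nb)
    denom[denom == 0] = 1.0
    S = (2.0 * fa @ fb.T - np.outer(na, nb)) / denom
    L1, L2 = S.shape
    NEG = -1e30
    M = np.full((L1 + 1, L2 + 1), NEG)
    IX = np.full((L1 + 1, L2 + 1), NEG)  # gap in B (consumes A)
    IY = np.full((L1 + 1, L2 + 1), NEG)  # gap in A (consumes B)
    M[0, 0] = 0.0
    IY[0, 1:] = _GAP_OPEN + _GAP_EXTEND * np.arange(L2)
    IX[1:, 0] = _GAP_OPEN + _GAP_EXTEND * np.arange(L1)
    for i in range(1, L1 + 1):
        prev_best = np.maximum(M[i - 1], np.maximum(IX[i - 1], IY[i - 1]))
        M[i, 1:] = S[i - 1] + prev_best[:-1]
        IX[i] = np.maximum(M[i - 1] + _GAP_OPEN, IX[i - 1] + _GAP_EXTEND)
        # IY scan along j via running max
        base = M[i, :-1] + _GAP_OPEN - _GAP_EXTEND * (np.arange(L2) + 1)
        IY[i, 1:] = np.maximum.accumulate(base) + _GAP_EXTEND * (np.arange(L2) + 1)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = L1, L2
    state = max(
        (("M", M[i, j]), ("IX", IX[i, j]), ("IY", IY[i, j])),
        key=lambda kv: kv[1],
    )[0]
    gap_a = "-" * len(rows_a)
    gap_b = "-" * len(rows_b)
    cols_a: list[str] = []
    cols_b: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            cols_a.append("".join(r[i - 1] for r in rows_a))
            cols_b.append("".join(r[j - 1] for r in rows_b))
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand in ("M", "IX", "IY"):
                val = {"M": M, "IX": IX, "IY": IY}[cand][i, j]
                if abs(val - prev) < tol:
                    state = cand
                    break
        elif state == "IX" and i > 0:
            cols_a.append("".join(r[i - 1] for r in rows_a))
            cols_b.append(gap_b)
            if abs(IX[i, j] - (M[i - 1, j] + _GAP_OPEN)) < tol:
                state = "M"
            i -= 1
        elif state == "IY" and j > 0:
            cols_a.append(gap_a)
            cols_b.append("".join(r[j - 1] for r in rows_b))
            if abs(IY[i, j] - (M[i, j - 1] + _GAP_OPEN)) < tol:
                state = "M"
            j -= 1
        else:  # boundary
            state = "IX" if i > 0 else "IY"
    cols_a.reverse()
    cols_b.reverse()
    for r in range(len(rows_a)):
        out_a.append("".join(col[r] for col in cols_a))
    for r in range(len(rows_b)):
        out_b.append("".join(col[r] for col in cols_b))
    return out_a, out_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(max(0, len(a) - k + 1))}
    kb = {b[i : i + k] for i in range(max(0, len(b) - k + 1))}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_msa(
    seqs: dict[str, str] | list[tuple[str, str]]
) -> MultipleAlignment:
    """Guide-tree progressive alignment.

    Pairwise k-mer distances feed a neighbor-joining guide tree (midpoint
    rooted); profiles are merged bottom-up with affine profile-profile
    alignment. Deterministic for fixed inputs.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("no sequences to align")
    if len(items) == 1:
        return MultipleAlignment(ids=(items[0][0],), rows=(items[0][1],))
    by_id = dict(items)
    if len(items) == 2:
        (ida, sa), (idb, sb) = items
        ra, rb = _align_profiles([ida], [sa], [idb], [sb])
        return MultipleAlignment(ids=(ida, idb), rows=(ra[0], rb[0]))
    ids = [k for k, _ in items]
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(items[i][1], items[j][1])
    tree = _skbio_nj(DistanceMatrix(dm, ids)).root_at_midpoint()

    def build(node) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [by_id[node.name]]
        child_profiles = [build(c) for c in node.children]
        ids_acc, rows_acc = child_profiles[0]
        for ids_b, rows_b in child_profiles[1:]:
            rows_acc, rows_b2 = _align_profiles(ids_acc, rows_acc, ids_b, rows_b)
            ids_acc = ids_acc + ids_b
            rows_acc = rows_acc + rows_b2
        return ids_acc, rows_acc

    out_ids, out_rows = build(tree)
    # restore input order
    order = {seq_id: i for i, seq_id in enumerate(out_ids)}
    pairs = sorted(zip(out_ids, out_rows), key=lambda kv: ids.index(kv[0]))
    return MultipleAlignment(
        ids=tuple(p[0] for p in pairs), rows=tuple(p[1] for p in pairs)
    )


def trim_sparse_columns(
    msa: MultipleAlignment,
    min_residue_fraction: float = DEFAULT_MIN_RESIDUE_FRACTION,
) -> MultipleAlignment:
    """Drop columns whose non-gap fraction is below the threshold.

    The boundary column (fraction exactly equal to the threshold) is kept,
    i.e. 'remove columns with more than 40% gaps' at the default 0.6.
    """
    nrow = len(msa.rows)
    keep = [
        c
        for c in range(msa.n_columns)
        if sum(1 for r in msa.rows if r[c] != "-") / nrow >= min_residue_fraction
    ]
    if not keep:
        raise ValueError("trimming removed every column")
    rows = tuple("".join(r[c] for c in keep) for r in msa.rows)
    return MultipleAlignment(ids=msa.ids, rows=rows)


def consensus(msa: MultipleAlignment) -> str:
    """Per-column plurality residue; ties break lexicographically; gaps don't vote."""
    if not msa.rows or msa.n_columns == 0:
        raise ValueError("empty alignment")
    out = []
    for c in range(msa.n_columns):
        counts: dict[str, int] = {}
        for r in msa.rows:
            ch = r[c]
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            out.append(max(sorted(counts), key=lambda ch: counts[ch]))
    return "".join(out)


def nj_tree(distance_matrix: np.ndarray, ids: list[str]) -> str:
    """Neighbor-joining tree in Newick, negative branch lengths clamped to 0."""
    dm = np.asarray(distance_matrix, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dm) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if len(ids) != dm.shape[0] or len(ids) < 2:
        raise ValueError("need one id per row and at least two taxa")
    if len(ids) == 2:
        half = dm[0, 1] / 2.0
        return f"({ids[0]}:{half:g},{ids[1]}:{half:g});"
    tree = _skbio_nj(DistanceMatrix(dm, ids))
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
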