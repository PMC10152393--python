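"""Profile HMMs for retroviral protein classification.

Parses HMMER3/f ASCII profiles, scores protein sequences with a local
(free entry/exit) uni-hit Viterbi algorithm in log-odds bits, and converts
bit scores to E-values through the Viterbi Gumbel calibration, so that
ORFs can be screened against an env/gag/pol profile database at a fixed
E-value threshold (1e-10 by default, the screening threshold used for
candidate envelope ORFs).

This is deliberately not a re-implementation of the full hmmscan pipeline:
there is no MSV/bias filter, no Forward score and no multi-domain chaining.
A single local alignment path is scored, with free begin->M_k entry and
M_k->end exit, and residues outside the aligned core contributing zero
log-odds (flank states score at background). 'X' residues emit at
background odds in every state, so N-rich ORFs are neither favored nor
penalized.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ALPHABET)}

# Standard amino-acid background frequencies (Swiss-Prot derived), the
# conventional null model for protein profile scoring.
AMINO_BACKGROUND = np.array(
    [
        0.0787945, 0.0151600, 0.0535222, 0.0668298, 0.0397062,
        0.0695071, 0.0229198, 0.0590092, 0.0594422, 0.0963728,
        0.0237718, 0.0414386, 0.0482904, 0.0395639, 0.0540978,
        0.0683364, 0.0540687, 0.0673417, 0.0114135, 0.0304133,
    ]
)
AMINO_BACKGROUND /= AMINO_BACKGROUND.sum()

LOG_ZERO = -1e30  # finite stand-in for log2(0); keeps DP arithmetic NaN-free

# transition tuple order, matching the HMMER3 file column order
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)


class HmmFormatError(ValueError):
    """Malformed HMMER3 ASCII input."""


@dataclass
class PhmmProfile:
    """A parsed profile HMM over the 20-letter amino-acid alphabet.

    ``match_emissions`` and ``insert_emissions`` are (M, 20) probability
    arrays for nodes 1..M; ``transitions`` is (M + 1, 7) with node 0 holding
    the begin-state row, columns ordered (M->M, M->I, M->D, I->M, I->I,
    D->M, D->D). ``calibration`` is the (mu, lambda) of the Viterbi-score
    Gumbel, or None for an uncalibrated profile.
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    null_model: np.ndarray = field(default_factory=lambda: AMINO_BACKGROUND.copy())
    calibration: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.calibration is not None and self.calibration[1] <= 0:
            raise ValueError("Gumbel lambda must be positive")
        self._score_cache: dict | None = None

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def is_calibrated(self) -> bool:
        return self.calibration is not None

    def validate(self, atol: float = 1e-6) -> None:
        for name, rows in (
            ("match", self.match_emissions),
            ("insert", self.insert_emissions),
        ):
            sums = rows.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"{name} emission rows do not sum to 1")
        t = self.transitions
        groups = {
            "M": t[:, [T_MM, T_MI, T_MD]].sum(axis=1),
            "I": t[:, [T_IM, T_II]].sum(axis=1),
            "D": t[1:, [T_DM, T_DD]].sum(axis=1),  # no D0 state
        }
        for name, sums in groups.items():
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"{name}-state transitions do not sum to 1")

    def consensus(self) -> str:
        return "".join(AMINO_ALPHABET[i] for i in self.match_emissions.argmax(axis=1))

    def _arrays(self):
        """Log-space (base 2) scoring arrays, cached."""
        if self._score_cache is None:
            with np.errstate(divide="ignore"):
                lo_match = np.log2(self.match_emissions / self.null_model)
                lo_ins = np.log2(self.insert_emissions / self.null_model)
                lt = np.log2(self.transitions)
            lo_match[~np.isfinite(lo_match)] = LOG_ZERO
            lo_ins[~np.isfinite(lo_ins)] = LOG_ZERO
            lt[~np.isfinite(lt)] = LOG_ZERO
            self._score_cache = {"lo_match": lo_match, "lo_ins": lo_ins, "lt": lt}
        return self._score_cache


@dataclass(frozen=True)
class PhmmHit:
    orf_id: str
    profile_name: str
    gene_class: str
    bit_score: float
    evalue: float


# --- Viterbi ----------------------------------------------------------------

def _encode(aa_seq: str) -> list[int]:
    # -1 encodes 'X'/unknown: zero log-odds everywhere
    return [_AA_INDEX.get(a, -1) for a in aa_seq.upper()]


def viterbi_score(profile: PhmmProfile, aa_seq: str) -> float:
    """Best local alignment score of ``aa_seq`` against the profile, in bits.

    Maximizes, over all begin->M_a ... M_b->end paths, the summed emission
    log-odds (match/insert emission vs the null model) plus transition
    log-probabilities. Entry and exit are free; unaligned flanking residues
    score zero.
    """
    if not aa_seq:
        raise ValueError("cannot score an empty sequence")
    arr = profile._arrays()
    lo_match, lo_ins, lt = arr["lo_match"], arr["lo_ins"], arr["lt"]
    M = profile.M
    # transitions out of node k live at row k; rows 1..M-1 feed nodes 2..M
    t_mm = lt[1:M, T_MM]
    t_mi = lt[1:M, T_MI]
    t_md = lt[1:M, T_MD]
    t_im = lt[1:M, T_IM]
    t_ii = lt[1:M, T_II]
    t_dm = lt[1:M, T_DM]
    t_dd = lt[1:M, T_DD]
    # prefix sums of log t(D_k -> D_k+1) for the vectorized delete chain
    cdd = np.concatenate([[0.0], np.cumsum(t_dd)])  # length M

    neg = np.full(M, LOG_ZERO)
    vm_prev = neg.copy()
    vi_prev = neg.copy()
    vd_prev = neg.copy()
    best = LOG_ZERO
    for xi in _encode(aa_seq):
        em = np.zeros(M) if xi < 0 else lo_match[:, xi]
        ei = np.zeros(M) if xi < 0 else lo_ins[:, xi]
        stay = np.maximum(
            vm_prev[:-1] + t_mm,
            np.maximum(vi_prev[:-1] + t_im, vd_prev[:-1] + t_dm),
        )
        vm = em + np.concatenate([[0.0], np.maximum(0.0, stay)])
        # I_k exists for nodes 1..M-1
        vi = neg.copy()
        vi[:-1] = ei[:-1] + np.maximum(
            vm_prev[:-1] + t_mi, vi_prev[:-1] + t_ii
        )
        # D chain within this row: VD[k] = max_{j<k} VM[j] + t_MD[j] + sum t_DD
        src = np.full(M, LOG_ZERO)
        src[1:] = vm[:-1] + t_md - cdd[1:]
        vd = np.maximum.accumulate(src) + cdd
        best = max(best, float(vm.max()))
        vm_prev, vi_prev, vd_prev = vm, vi, vd
    return best


def evalue(profile: PhmmProfile, bits: float, db_size: int) -> float:
    """Expected false positives at this score, from the Viterbi Gumbel tail."""
    if not profile.is_calibrated:
        raise ValueError(f"profile {profile.name!r} is not calibrated")
    if db_size < 1:
        raise ValueError("db_size must be >= 1")
    mu, lam = profile.calibration
    p = -math.expm1(-math.exp(-lam * (bits - mu)))
    return db_size * p


def classify_orfs(
    orfs: Sequence,
    profiles: Sequence[PhmmProfile],
    class_map: Mapping[str, str] | None = None,
    e_threshold: float = 1e-10,
) -> list[PhmmHit]:
    """Score each ORF against all profiles; keep the best hit iff E <= threshold.

    ``orfs`` may be OrfRecord objects or (id, aa_seq) pairs; ``class_map``
    maps profile name -> gene class (env/gag/pro/pol), defaulting to the
    profile name itself.
    """
    if not profiles:
        raise ValueError("empty profile set")
    db_size = len(profiles)
    hits: list[PhmmHit] = []
    for orf in orfs:
        if isinstance(orf, tuple):
            orf_id, aa_seq = orf
        else:
            orf_id, aa_seq = orf.id, orf.aa_seq
        aa_seq = aa_seq.rstrip("*")
        best: tuple[float, PhmmProfile] | None = None
        for prof in profiles:
            bits = viterbi_score(prof, aa_seq)
            if best is None or bits > best[0]:
                best = (bits, prof)
        bits, prof = best
        e = evalue(prof, bits, db_size)
        if e <= e_threshold:
            gene_class = (class_map or {}).get(prof.name, prof.name)
            hits.append(PhmmHit(orf_id, prof.name, gene_class, bits, e))
    return hits


# --- HMMER3 ASCII I/O -------------------------------------------------------

def _prob(tok: str, lineno: int) -> float:
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError as exc:
        raise HmmFormatError(f"line {lineno}: bad probability token {tok!r}") from exc


def parse_hmmer3(path: str | Path) -> list[PhmmProfile]:
    """Parse all profiles from a HMMER3/f ASCII file.

    Emission and transition probabilities are recovered from the file's
    negative-natural-log encoding; a ``STATS LOCAL VITERBI`` line supplies
    the Gumbel (mu, lambda). Profiles without one are returned uncalibrated.
    """
    lines = Path(path).read_text().splitlines()
    profiles: list[PhmmProfile] = []
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("HMMER3"):
            raise HmmFormatError(f"line {i + 1}: expected HMMER3 header")
        i += 1
        name = None
        leng = None
        calibration = None
        while i < n and not lines[i].startswith("HMM "):
            fields = lines[i].split()
            if not fields:
                raise HmmFormatError(f"line {i + 1}: blank line inside header")
            if fields[0] == "NAME":
                name = fields[1]
            elif fields[0] == "LENG":
                leng = int(fields[1])
            elif fields[0] == "ALPH" and fields[1].lower() != "amino":
                raise HmmFormatError(f"line {i + 1}: only amino profiles supported")
            elif fields[0] == "STATS" and fields[1:3] == ["LOCAL", "VITERBI"]:
                calibration = (float(fields[3]), float(fields[4]))
            i += 1
        if i >= n or name is None or leng is None:
            raise HmmFormatError(f"line {i + 1}: truncated profile header")
        header_syms = lines[i].split()[1:]
        if "".join(header_syms) != AMINO_ALPHABET:
            raise HmmFormatError(f"line {i + 1}: unexpected alphabet ordering")
        i += 2  # skip the transition-name line
        if i < n and lines[i].split()[:1] == ["COMPO"]:
            i += 1
        if i + 1 >= n:
            raise HmmFormatError(f"line {n}: truncated node-0 block")
        # node 0: insert emissions + begin transitions
        ins0 = [_prob(t, i + 1) for t in lines[i].split()]
        i += 1
        t0 = [_prob(t, i + 1) for t in lines[i].split()]
        i += 1
        if len(ins0) != 20 or len(t0) != 7:
            raise HmmFormatError(f"line {i}: malformed node-0 block")
        match_em = np.zeros((leng, 20))
        ins_em = np.zeros((leng, 20))
        trans = np.zeros((leng + 1, 7))
        trans[0] = t0
        for k in range(1, leng + 1):
            if i + 2 >= n:
                raise HmmFormatError(f"line {n}: truncated at node {k}")
            fields = lines[i].split()
            if not fields or fields[0] != str(k):
                raise HmmFormatError(f"line {i + 1}: expected node {k}")
            match_em[k - 1] = [_prob(t, i + 1) for t in fields[1:21]]
            ins_em[k - 1] = [_prob(t, i + 2) for t in lines[i + 1].split()[:20]]
            trow = [_prob(t, i + 3) for t in lines[i + 2].split()[:7]]
            if len(trow) != 7:
                raise HmmFormatError(f"line {i + 3}: malformed transition row")
            trans[k] = trow
            i += 3
        if i >= n or lines[i].strip() != "//":
            raise HmmFormatError(f"line {i + 1}: expected '//' terminator")
        i += 1
        # insert emissions default to node-0 values for display-only rows
        profiles.append(
            PhmmProfile(
                name=name,
                match_emissions=match_em,
                insert_emissions=ins_em,
                transitions=trans,
                calibration=calibration,
            )
        )
    if not profiles:
        raise HmmFormatError("no profiles found")
    return profiles


def _fmt(p: float) -> str:
    return "      *" if p <= 0 else f"{-math.log(p):.5f}"


def write_hmmer3(profiles: Iterable[PhmmProfile], path: str | Path) -> None:
    """Write profiles in HMMER3/f ASCII, readable by this parser and by HMMER."""
    out = []
    for prof in profiles:
        M = prof.M
        out.append("HMMER3/f [3.4 | erv-env-miner]")
        out.append(f"NAME  {prof.name}")
        out.append(f"LENG  {M}")
        out.append("ALPH  amino")
        out.append("RF    no")
        out.append("MM    no")
        out.append("CONS  yes")
        out.append("CS    no")
        out.append("MAP   yes")
        if prof.calibration is not None:
            mu, lam = prof.calibration
            out.append(f"STATS LOCAL MSV     {mu:8.4f} {lam:8.5f}")
            out.append(f"STATS LOCAL VITERBI {mu:8.4f} {lam:8.5f}")
            out.append(f"STATS LOCAL FORWARD {mu:8.4f} {lam:8.5f}")
        out.append(
            "HMM          "
            + "        ".join(AMINO_ALPHABET)
        )
        out.append(
            "            m->m     m->i     m->d     i->m     i->i     d->m     d->d"
        )
        compo = prof.match_emissions.mean(axis=0)
        out.append("  COMPO   " + "  ".join(_fmt(p) for p in compo))
        out.append("          " + "  ".join(_fmt(p) for p in prof.insert_emissions[0]))
        out.append("          " + "  ".join(_fmt(p) for p in prof.transitions[0]))
        cons = prof.consensus()
        for k in range(1, M + 1):
            row = "  ".join(_fmt(p) for p in prof.match_emissions[k - 1])
            out.append(f"{k:7d}   {row} {k:6d} {cons[k - 1].lower()} - - -")
            out.append(
                "          " + "  ".join(_fmt(p) for p in prof.insert_emissions[k - 1])
            )
            out.append("          " + "  ".join(_fmt(p) for p in prof.transitions[k]))
        out.append("//")
    Path(path).write_text("\n".join(out) + "\n")


# --- profile construction and calibration -----------------------------------

def profile_from_sequence(
    name: str,
    aa_seq: str,
    match_major: float = 0.9,
    t_mm: float = 0.96,
    t_mi: float = 0.02,
    t_md: float = 0.02,
) -> PhmmProfile:
    """Build a simple profile whose match states favor a template sequence.

    Each match state emits the template residue with probability
    ``match_major`` and the remaining mass uniformly; insert states emit at
    the background. Useful for synthetic benchmark profile databases and
    test fixtures; calibrate with :func:`calibrate_profile` before computing
    E-values.
    """
    aa_seq = aa_seq.rstrip("*")
    if not aa_seq or any(a not in _AA_INDEX for a in aa_seq):
        raise ValueError("template must be non-empty over the 20-letter alphabet")
    M = len(aa_seq)
    match = np.full((M, 20), (1.0 - match_major) / 19.0)
    for k, a in enumerate(aa_seq):
        match[k, _AA_INDEX[a]] = match_major
    ins = np.tile(AMINO_BACKGROUND, (M, 1))
    trans = np.zeros((M + 1, 7))
    trans[0] = [1.0, 0.0, 0.0, 0.5, 0.5, 0.0, 0.0]  # begin -> M1
    trans[1:M] = [t_mm, t_mi, t_md, 0.5, 0.5, 0.8, 0.2]
    trans[M] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]  # node M: exits to end
    return PhmmProfile(
        name=name, match_emissions=match, insert_emissions=ins, transitions=trans
    )


def calibrate_profile(
    profile: PhmmProfile,
    seed: int,
    n_samples: int = 200,
    seq_len: int | None = None,
    lam: float = math.log(2.0),
) -> PhmmProfile:
    """Estimate the Viterbi Gumbel location by simulation.

    Scores ``n_samples`` i.i.d. background sequences and fits mu by maximum
    likelihood with lambda fixed at ln 2 — the conventional slope for
    well-behaved bit scores. Sets ``profile.calibration`` in place and
    returns the profile.
    """
    rng = np.random.default_rng(seed)
    L = seq_len if seq_len is not None else max(2 * profile.M, 100)
    scores = []
    for _ in range(n_samples):
        idx = rng.choice(20, size=L, p=profile.null_model)
        seq = "".join(AMINO_ALPHABET[i] for i in idx)
        scores.append(viterbi_score(profile, seq))
    scores = np.array(scores)
    # Gumbel MLE for mu with known lambda
    mu = math.log(n_samples / np.exp(-lam * scores).sum()) / lam
    profile.calibration = (mu, lam)
    return profile


def read_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (profile name, gene class) TSV mapping."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = re.split(r"\s+", line)
        if len(fields) < 2:
            raise ValueError(f"malformed class-map line: {line!r}")
        mapping[fields[0]] = fields[1]
    return mapping
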