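"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written as direct enumeration or naive
scanning, structured differently from the package implementations it
checks: ORF discovery walks codons explicitly instead of translating and
splitting; profile-HMM scoring enumerates every state path instead of
running the DP; alignment scoring is a plain quadratic DP without affine
state decomposition.
"""

from __future__ import annotations


import numpy as np

from erv_env_miner.profile_hmm import (
    LOG_ZERO,
    PhmmProfile,
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
    _AA_INDEX,
)

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# standard codon table, written out independently of the package's
_CODONS = {}
_BASES = "TCAG"
_AA_ORDER = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODONS[_b1 + _b2 + _b3] = _AA_ORDER[16 * _i + 4 * _j + _k]


def orf_scan(seq: str, min_codons: int, mode: str = "start_to_stop"):
    """Naive six-frame ORF scan.

    Returns a set of (start, end, strand, frame) tuples on forward-strand
    coordinates, end exclusive and including the terminal stop codon when
    present, matching the package's reporting convention.
    """
    results = set()
    L = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else "".join(_COMP[c] for c in reversed(seq))
        for frame in range(3):
            codon_starts = list(range(frame, len(s) - 2, 3))
            seg_begin = 0  # codon index where the current segment starts
            idx = 0
            n_codons = len(codon_starts)
            while idx <= n_codons:
                at_stop = idx < n_codons and s[
                    codon_starts[idx] : codon_starts[idx] + 3
                ] in _STOPS
                if at_stop or idx == n_codons:
                    has_stop = at_stop
                    seg_end = idx  # exclusive, codon units
                    if mode == "start_to_stop":
                        first_atg = None
                        for c in range(seg_begin, seg_end):
                            if s[codon_starts[c] : codon_starts[c] + 3] == "ATG":
                                first_atg = c
                                break
                        spans = (
                            [(first_atg, seg_end)] if first_atg is not None else []
                        )
                    else:
                        spans = [(seg_begin, seg_end)] if seg_end > seg_begin else []
                    for c0, c1 in spans:
                        aa_len = c1 - c0
                        if aa_len < min_codons:
                            continue
                        nt_start = codon_starts[c0]
                        nt_end = codon_starts[c1 - 1] + 3 + (3 if has_stop else 0)
                        if strand == "+":
                            results.add((nt_start, nt_end, strand, frame))
                        else:
                            results.add((L - nt_end, L - nt_start, strand, frame))
                    seg_begin = idx + 1
                idx += 1
    return results


def enumerate_viterbi(profile: PhmmProfile, seq: str) -> float:
    """Exhaustive enumeration of every local alignment path, in bits.

    Feasible only for tiny profiles and sequences; the primary correctness
    oracle for the Viterbi DP.
    """
    M = profile.M
    with np.errstate(divide="ignore"):
        lo_m = np.log2(profile.match_emissions / profile.null_model)
        lo_i = np.log2(profile.insert_emissions / profile.null_model)
        lt = np.log2(profile.transitions)
    for arr in (lo_m, lo_i, lt):
        arr[~np.isfinite(arr)] = LOG_ZERO
    x = [_AA_INDEX.get(c, -1) for c in seq]
    L = len(x)

    def em(table, k, xi):
        return 0.0 if xi < 0 else table[k - 1, xi]

    best = [LOG_ZERO]

    def walk(state: str, k: int, i: int, score: float) -> None:
        # state machine over (M_k, I_k, D_k); i = residues consumed so far
        if state == "M":
            best[0] = max(best[0], score)  # free exit from any match state
        if i < L:
            if state == "M" and k < M:
                walk("M", k + 1, i + 1, score + lt[k, T_MM] + em(lo_m, k + 1, x[i]))
            if state == "M" and k < M:
                walk("I", k, i + 1, score + lt[k, T_MI] + em(lo_i, k, x[i]))
            if state == "I":
                walk("M", k + 1, i + 1, score + lt[k, T_IM] + em(lo_m, k + 1, x[i]))
                walk("I", k, i + 1, score + lt[k, T_II] + em(lo_i, k, x[i]))
            if state == "D" and k < M:
                walk("M", k + 1, i + 1, score + lt[k, T_DM] + em(lo_m, k + 1, x[i]))
        if state == "M" and k < M:
            walk("D", k + 1, i, score + lt[k, T_MD])
        if state == "D" and k < M:
            walk("D", k + 1, i, score + lt[k, T_DD])

    for a in range(L):  # entry residue
        for k in range(1, M + 1):  # entry node, free begin -> M_k
            walk("M", k, a + 1, em(lo_m, k, x[a]))
    return best[0]


def gumbel_evalue(mu: float, lam: float, bits: float, db_size: int) -> float:
    """E-value from the Gumbel survival function, via scipy."""
    from scipy.stats import gumbel_r

    return db_size * gumbel_r.sf(bits, loc=mu, scale=1.0 / lam)


def linear_gap_nw_score(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Plain global-alignment DP with per-column gap cost (no affine states)."""
    la, lb = len(a), len(b)
    dp = np.zeros((la + 1, lb + 1))
    dp[:, 0] = gap * np.arange(la + 1)
    dp[0, :] = gap * np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + sub, dp[i - 1, j] + gap, dp[i, j - 1] + gap)
    return float(dp[la, lb])


def alignment_score(aligned_a: str, aligned_b: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float) -> float:
    """Score an explicit alignment under the affine scheme (first gap column
    costs gap_open, subsequent ones gap_extend)."""
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-":
            score += gap_extend if prev_gap_a else gap_open
            prev_gap_a, prev_gap_b = True, False
        elif cb == "-":
            score += gap_extend if prev_gap_b else gap_open
            prev_gap_a, prev_gap_b = False, True
        else:
            score += match if ca == cb else mismatch
            prev_gap_a = prev_gap_b = False
    return score


def toy_profiles(seed: int = 7) -> list[PhmmProfile]:
    """Small dense profiles (M <= 3) with varied transition structure."""
    rng = np.random.default_rng(seed)
    profiles = []
    for idx, M in enumerate((1, 2, 3)):
        match = rng.dirichlet(np.full(20, 0.5), size=M)
        ins = rng.dirichlet(np.full(20, 5.0), size=M)
        trans = np.zeros((M + 1, 7))
        trans[0] = [1.0, 0.0, 0.0, 0.5, 0.5, 0.0, 0.0]
        for k in range(1, M):
            mm = rng.dirichlet([8.0, 1.0, 1.0])
            im = rng.dirichlet([2.0, 1.0])
            dm = rng.dirichlet([2.0, 1.0])
            trans[k] = [*mm, *im, *dm]
        trans[M] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]
        profiles.append(
            PhmmProfile(
                name=f"toy{idx}",
                match_emissions=match,
                insert_emissions=ins,
                transitions=trans,
            )
        )
    return profiles
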