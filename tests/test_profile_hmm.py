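"""Profile-HMM parsing, Viterbi scoring and E-value calibration."""

import itertools
import math

import numpy as np
import pytest

from erv_env_miner.profile_hmm import (
    AMINO_ALPHABET,
    AMINO_BACKGROUND,
    HmmFormatError,
    PhmmProfile,
    calibrate_profile,
    classify_orfs,
    evalue,
    parse_hmmer3,
    profile_from_sequence,
    viterbi_score,
    write_hmmer3,
)

from _oracles import enumerate_viterbi, gumbel_evalue, toy_profiles


def _single_state_profile(bits: float = 2.0) -> PhmmProfile:
    """M=1 profile whose match state emits 'A' at the requested log-odds."""
    null = AMINO_BACKGROUND
    p_a = null[0] * 2.0**bits
    match = np.full((1, 20), (1 - p_a) / 19)
    match[0, 0] = p_a
    trans = np.array(
        [[1, 0, 0, 0.5, 0.5, 0, 0], [1, 0, 0, 1, 0, 1, 0]], dtype=float
    )
    return PhmmProfile("one", match, np.tile(null, (1, 1)), trans)


class TestViterbi:
    def test_single_match_state_scores_its_residue(self):
        prof = _single_state_profile(bits=2.0)
        assert viterbi_score(prof, "A") == pytest.approx(2.0)

    def test_flanking_residues_are_free(self):
        prof = _single_state_profile(bits=2.0)
        assert viterbi_score(prof, "CCACC") == pytest.approx(2.0)
        assert viterbi_score(prof, "A" + "X" * 10) == pytest.approx(2.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            viterbi_score(_single_state_profile(), "")

    def test_matches_exhaustive_path_enumeration(self):
        """DP equals brute-force enumeration for all toy instances."""
        alphabet = "ACDE"
        for prof in toy_profiles():
            for L in range(1, 5):
                for letters in itertools.product(alphabet, repeat=L):
                    seq = "".join(letters)
                    assert viterbi_score(prof, seq) == pytest.approx(
                        enumerate_viterbi(prof, seq), abs=1e-9
                    ), (prof.name, seq)

    def test_mismatch_never_increases_score(self):
        template = "ACDEFGHIKLMNPQRSTVWY" * 3
        prof = profile_from_sequence("t", template)
        base = viterbi_score(prof, template)
        for pos in (0, 10, 30, 59):
            mutated = list(template)
            mutated[pos] = "A" if mutated[pos] != "A" else "C"
            assert viterbi_score(prof, "".join(mutated)) <= base + 1e-9


class TestEvalue:
    def test_direct_formula_value(self):
        prof = _single_state_profile()
        prof.calibration = (0.0, 0.693)
        assert evalue(prof, 10.0, 1) == pytest.approx(9.77e-4, rel=1e-3)

    def test_at_mu_gives_63_percent_of_db(self):
        prof = _single_state_profile()
        prof.calibration = (5.0, 0.7)
        assert evalue(prof, 5.0, 10) == pytest.approx(10 * (1 - math.exp(-1)))

    def test_linear_in_db_size(self):
        prof = _single_state_profile()
        prof.calibration = (3.0, 0.7)
        assert evalue(prof, 9.0, 20) == pytest.approx(2 * evalue(prof, 9.0, 10))

    def test_agrees_with_scipy_gumbel_tail(self):
        prof = _single_state_profile()
        prof.calibration = (-9.0, 0.7)
        for bits in (-12.0, -9.0, 0.0, 10.0, 40.0):
            assert evalue(prof, bits, 7) == pytest.approx(
                gumbel_evalue(-9.0, 0.7, bits, 7), rel=1e-9, abs=1e-300
            )

    def test_uncalibrated_profile_rejected(self):
        with pytest.raises(ValueError, match="not calibrated"):
            evalue(_single_state_profile(), 10.0, 1)

    def test_monotone_nonincreasing_in_bits(self):
        prof = _single_state_profile()
        prof.calibration = (0.0, 0.693)
        es = [evalue(prof, b, 5) for b in np.linspace(-5, 60, 40)]
        assert all(a >= b for a, b in zip(es, es[1:]))


class TestClassification:
    def test_threshold_keeps_and_discards(self):
        # same 2-bit hit; the calibration places its E on either side of 1e-10
        prof_hot = _single_state_profile(bits=2.0)
        prof_hot.calibration = (-50.0, math.log(2))  # E ~ 2^-52 <= 1e-10
        hits = classify_orfs([("s", "A")], [prof_hot], e_threshold=1e-10)
        assert len(hits) == 1 and hits[0].evalue <= 1e-10
        prof_cold = _single_state_profile(bits=2.0)
        prof_cold.calibration = (-20.0, math.log(2))  # E ~ 2^-22 > 1e-10
        assert classify_orfs([("s", "A")], [prof_cold], e_threshold=1e-10) == []

    def test_empty_orf_list_and_empty_profiles(self):
        prof = _single_state_profile()
        assert classify_orfs([], [prof]) == []
        with pytest.raises(ValueError):
            classify_orfs([("s", "A")], [])

    def test_planted_template_hits_and_shuffled_misses(self):
        rng = np.random.default_rng(123)
        template = "".join(
            AMINO_ALPHABET[i] for i in rng.integers(0, 20, size=300)
        )
        prof = profile_from_sequence("env_toy", template)
        calibrate_profile(prof, seed=5, n_samples=60, seq_len=300)
        shuffled = "".join(rng.permutation(list(template)))
        hits = classify_orfs(
            [("real", template), ("shuf", shuffled)],
            [prof],
            {"env_toy": "env"},
            e_threshold=1e-10,
        )
        assert [h.orf_id for h in hits] == ["real"]
        assert hits[0].gene_class == "env"


TOY_HMM = """\
HMMER3/f [3.4 | test]
NAME  toy2
LENG  2
ALPH  amino
STATS LOCAL VITERBI -9.0 0.7
HMM          A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y
            m->m     m->i     m->d     i->m     i->i     d->m     d->d
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  3.07961
          0.00000        *        *  0.69315  0.69315        *        *
      1   0.10536  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  4.48075  3.62434      1 a - - -
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  3.07961
          0.01005  5.00000  5.29832  0.69315  0.69315  0.40048  1.10866
      2   3.00000  0.10536  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  3.00000  4.48075  3.62434      2 c - - -
          2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  3.07961
          0.00000        *        *  0.00000        *  0.00000        *
//
"""


class TestParser:
    def test_hand_written_profile_fields(self, tmp_path):
        path = tmp_path / "toy.hmm"
        path.write_text(TOY_HMM)
        (prof,) = parse_hmmer3(path)
        assert prof.name == "toy2" and prof.M == 2
        assert prof.calibration == (-9.0, 0.7)
        assert prof.match_emissions[0, 0] == pytest.approx(math.exp(-0.10536))
        assert prof.match_emissions[1, 1] == pytest.approx(math.exp(-0.10536))
        assert prof.transitions[1, 0] == pytest.approx(math.exp(-0.01005))
        assert prof.transitions[2, 1] == 0.0  # '*' encodes probability zero

    def test_missing_stats_line_means_uncalibrated(self, tmp_path):
        text = "\n".join(
            line for line in TOY_HMM.splitlines() if not line.startswith("STATS")
        )
        path = tmp_path / "toy.hmm"
        path.write_text(text + "\n")
        (prof,) = parse_hmmer3(path)
        assert not prof.is_calibrated

    def test_truncated_file_raises_with_line_number(self, tmp_path):
        path = tmp_path / "trunc.hmm"
        path.write_text("\n".join(TOY_HMM.splitlines()[:8]) + "\n")
        with pytest.raises(HmmFormatError, match="line"):
            parse_hmmer3(path)

    def test_write_parse_round_trip(self, tmp_path):
        prof = profile_from_sequence("rt", "ACDEFGHIKLMNPQRSTVWY")
        prof.calibration = (-4.5, math.log(2))
        path = tmp_path / "rt.hmm"
        write_hmmer3([prof], path)
        (back,) = parse_hmmer3(path)
        assert back.name == "rt"
        np.testing.assert_allclose(
            back.match_emissions, prof.match_emissions, atol=1e-5
        )
        np.testing.assert_allclose(back.transitions, prof.transitions, atol=1e-5)
        assert back.calibration == pytest.approx(prof.calibration, abs=1e-4)
        back.validate(atol=1e-4)


class TestPyhmmerCrossCheck:
    """Rank-order agreement with an independent HMMER implementation."""

    def test_written_profiles_load_and_rank_consistently(self, tmp_path):
        pyhmmer = pytest.importorskip("pyhmmer")
        rng = np.random.default_rng(9)
        template = "".join(
            AMINO_ALPHABET[i] for i in rng.integers(0, 20, size=200)
        )
        prof = profile_from_sequence("xcheck", template)
        calibrate_profile(prof, seed=2, n_samples=60, seq_len=200)
        path = tmp_path / "x.hmm"
        write_hmmer3([prof], path)
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            hmm = fh.read()
        name = hmm.name if isinstance(hmm.name, str) else hmm.name.decode()
        assert name == "xcheck" and hmm.M == 200
        alpha = pyhmmer.easel.Alphabet.amino()
        bg = pyhmmer.plan7.Background(alpha)
        pipeline = pyhmmer.plan7.Pipeline(alpha, background=bg, E=1e6)
        shuffled = "".join(rng.permutation(list(template)))
        seqs = [
            pyhmmer.easel.TextSequence(name=b"real", sequence=template),
            pyhmmer.easel.TextSequence(name=b"shuf", sequence=shuffled),
        ]
        hits = pipeline.search_hmm(
            hmm, pyhmmer.easel.DigitalSequenceBlock(
                alpha, [s.digitize(alpha) for s in seqs]
            )
        )
        scores = {
            (h.name if isinstance(h.name, str) else h.name.decode()): h.score
            for h in hits
        }
        ours = {
            "real": viterbi_score(prof, template),
            "shuf": viterbi_score(prof, shuffled),
        }
        assert scores["real"] > scores.get("shuf", -1e9)
        assert ours["real"] > ours["shuf"]
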