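"""Family clustering, progressive MSA, trimming, consensus and NJ trees."""

import io
import shutil
import subprocess

import numpy as np
import pytest
from skbio import TreeNode

from erv_env_miner.families_consensus import (
    MultipleAlignment,
    cluster_families,
    consensus,
    nj_tree,
    pairwise_identity,
    progressive_msa,
    trim_sparse_columns,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _mutate(seq, n_sub, rng):
    out = list(seq)
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    for p in pos:
        out[p] = rng.choice([a for a in AA if a != out[p]])
    return "".join(out)


class TestClusterFamilies:
    def test_identical_pair_one_family(self):
        fams = cluster_families({"a": "MKLV" * 30, "b": "MKLV" * 30})
        assert len(fams) == 1 and fams[0].copy_number == 2

    def test_divergent_pair_two_families(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(AA, size=120))
        b = _mutate(a, 60, rng)  # 50% identity
        fams = cluster_families({"a": a, "b": b}, identity_threshold=80.0)
        assert len(fams) == 2

    def test_single_linkage_chains_transitively(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(AA, size=100))
        b = _mutate(a, 15, rng)  # a~b 85%
        # c differs from b at 15 *other* positions -> a~c ~70%
        c = list(b)
        pos_ab = {i for i in range(100) if a[i] != b[i]}
        free = [i for i in range(100) if i not in pos_ab]
        for p in rng.choice(free, size=15, replace=False):
            c[p] = rng.choice([x for x in AA if x != c[p]])
        c = "".join(c)
        assert pairwise_identity(a, b) >= 80
        assert pairwise_identity(b, c) >= 80
        assert pairwise_identity(a, c) < 80
        fams = cluster_families({"a": a, "b": b, "c": c})
        assert len(fams) == 1 and fams[0].copy_number == 3

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(2)
        base1 = "".join(rng.choice(AA, size=90))
        base2 = "".join(rng.choice(AA, size=90))
        seqs = {
            f"c:{i * 100}-{i * 100 + 90}(+)": _mutate(
                base1 if i < 3 else base2, 5, rng
            )
            for i in range(6)
        }
        fams1 = cluster_families(seqs)
        shuffled = dict(reversed(list(seqs.items())))
        fams2 = cluster_families(shuffled)
        assert [f.members for f in fams1] == [f.members for f in fams2]
        all_members = [m for f in fams1 for m in f.members]
        assert sorted(all_members) == sorted(seqs)

    def test_naming_by_copy_number_then_position(self):
        rng = np.random.default_rng(3)
        big = "".join(rng.choice(AA, size=80))
        small = "".join(rng.choice(AA, size=80))
        seqs = {
            "c:100-180(+)": small,
            "c:500-580(+)": big,
            "c:900-980(+)": _mutate(big, 4, rng),
        }
        fams = cluster_families(seqs)
        assert fams[0].copy_number == 2 and fams[0].name.endswith("1")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_families({})


class TestProgressiveMsa:
    def test_identical_sequences_align_gap_free(self):
        msa = progressive_msa({f"s{i}": "MKVLLAV" * 10 for i in range(4)})
        assert msa.n_columns == 70
        assert all("-" not in row for row in msa.rows)

    def test_single_sequence_returned_unchanged(self):
        msa = progressive_msa({"only": "MKVL"})
        assert msa.rows == ("MKVL",)

    def test_single_indel_yields_one_gap_column(self):
        a = "MKVLDEAVRKLVDE"
        b = a[:7] + a[8:]  # one residue deleted
        msa = progressive_msa({"a": a, "b": b})
        assert msa.n_columns == len(a)
        assert msa.rows[1].count("-") == 1

    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(AA, size=120))
        seqs = {}
        for i in range(5):
            s = list(_mutate(base, 6, rng))
            if i % 2:
                del s[int(rng.integers(0, len(s)))]
            seqs[f"s{i}"] = "".join(s)
        msa = progressive_msa(seqs)
        for i, sid in enumerate(msa.ids):
            assert msa.degapped(i) == seqs[sid]

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(AA, size=80))
        seqs = {f"s{i}": _mutate(base, 5, rng) for i in range(4)}
        assert progressive_msa(seqs) == progressive_msa(seqs)

    @pytest.mark.skipif(shutil.which("mafft") is None, reason="mafft not on PATH")
    def test_consensus_agrees_with_mafft_alignment(self, tmp_path):
        """Sanity cross-check against an external aligner on one family."""
        rng = np.random.default_rng(6)
        base = "".join(rng.choice(AA, size=150))
        seqs = {f"s{i}": _mutate(base, 8, rng) for i in range(5)}
        fasta = tmp_path / "f.faa"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        out = subprocess.run(
            ["mafft", "--quiet", str(fasta)], capture_output=True, text=True
        )
        rows, ids, cur = [], [], []
        for line in out.stdout.splitlines():
            if line.startswith(">"):
                ids.append(line[1:])
                if cur:
                    rows.append("".join(cur))
                cur = []
            else:
                cur.append(line)
        rows.append("".join(cur))
        theirs = consensus(MultipleAlignment(tuple(ids), tuple(r.upper() for r in rows)))
        ours = consensus(progressive_msa(seqs))
        assert pairwise_identity(ours, theirs) >= 99.0


class TestTrimAndConsensus:
    def test_sparse_column_removed_boundary_kept(self):
        msa = MultipleAlignment(
            ids=("a", "b", "c", "d", "e"),
            rows=("AK", "AK", "A-", "-K", "-K"),
        )
        # col 0: 3/5 = 60% kept; col 1: 4/5 kept
        trimmed = trim_sparse_columns(msa, 0.6)
        assert trimmed.n_columns == 2
        sparser = MultipleAlignment(
            ids=("a", "b", "c", "d", "e"),
            rows=("AK", "AK", "--", "-K", "-K"),
        )
        # col 0 now 2/5 = 40% < 60% -> removed
        assert trim_sparse_columns(sparser, 0.6).n_columns == 1

    def test_gap_free_alignment_unchanged(self):
        msa = MultipleAlignment(("a", "b"), ("MKV", "MRV"))
        assert trim_sparse_columns(msa) == msa

    def test_all_columns_removed_is_error(self):
        msa = MultipleAlignment(("a", "b", "c"), ("A--", "-A-", "--A"))
        with pytest.raises(ValueError):
            trim_sparse_columns(msa, 0.6)

    def test_consensus_of_identical_rows(self):
        for k in (1, 2, 5):
            msa = MultipleAlignment(
                tuple(f"s{i}" for i in range(k)), tuple(["MKVL"] * k)
            )
            assert consensus(trim_sparse_columns(msa)) == "MKVL"

    def test_plurality_and_lexicographic_tie(self):
        msa = MultipleAlignment(("a", "b", "c"), ("AAT", "ATT", "TTA"))
        # col0 {A,A,T}->A; col1 {A,T,T}->T; col2 {T,T,A}->T
        assert consensus(msa) == "ATT"
        tie = MultipleAlignment(("a", "b"), ("A", "T"))
        assert consensus(tie) == "A"

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            consensus(MultipleAlignment((), ()))


class TestNjTree:
    def _tip_depths(self, newick):
        tree = TreeNode.read(io.StringIO(newick))
        return tree, {t.name: t.length for t in tree.tips()}

    def test_three_taxa_closed_form(self):
        dm = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree, _ = self._tip_depths(nj_tree(dm, ["A", "B", "C"]))
        dist = {}
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            dist[(a, b)] = tree.find(a).distance(tree.find(b))
        assert dist[("A", "B")] == pytest.approx(2)
        assert dist[("A", "C")] == pytest.approx(4)
        assert dist[("B", "C")] == pytest.approx(4)

    def test_two_taxa_cherry(self):
        newick = nj_tree(np.array([[0, 3.0], [3.0, 0]]), ["A", "B"])
        assert newick == "(A:1.5,B:1.5);"

    def test_additive_four_taxon_distances_recovered_exactly(self):
        # tree ((A:1,B:2):1,C:3,D:4) gives an additive matrix
        dm = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            float,
        )
        tree, _ = self._tip_depths(nj_tree(dm, ["A", "B", "C", "D"]))
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                        dm[i, j]
                    )

    def test_asymmetric_matrix_rejected(self):
        dm = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(dm, ["A", "B", "C"])

    def test_negative_branch_lengths_clamped_with_warning(self):
        dm = np.array(
            [[0, 0.1, 0.6, 0.6], [0.1, 0, 0.65, 0.6],
             [0.6, 0.65, 0, 0.1], [0.6, 0.6, 0.1, 0]]
        )
        # not guaranteed negative; construct a strongly non-additive matrix
        dm2 = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 0.2], [9, 10, 0.2, 0]]
        )
        for mat in (dm, dm2):
            newick = nj_tree(mat, ["A", "B", "C", "D"])
            tree = TreeNode.read(io.StringIO(newick))
            assert all(
                n.length is None or n.length >= 0 for n in tree.traverse()
            )
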