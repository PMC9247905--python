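import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from foldswitch.seqcore import (IdentityMatrix, Sequence, cluster_by_identity,
                                identity_matrix, identity_stats, local_align,
                                pairwise_identity, read_fasta, write_fasta)


def seq(residues, sid="s"):
    return Sequence(id=sid, residues=residues)


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">s1\nACDE\n")
        out = read_fasta(p)
        assert len(out) == 1
        assert out[0].id == "s1" and out[0].residues == "ACDE"

    def test_two_records_order_preserved(self, tmp_path):
        p = tmp_path / "two.fasta"
        p.write_text(">s1 first\nACDE\n>s2 second\nKLMN\n")
        out = read_fasta(p)
        assert [s.id for s in out] == ["s1", "s2"]
        assert out[0].description == "first"

    def test_lowercase_normalised(self, tmp_path, caplog):
        p = tmp_path / "lc.fasta"
        p.write_text(">s1\nacde\n")
        assert read_fasta(p)[0].residues == "ACDE"

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_roundtrip(self, tmp_path):
        seqs = [seq("ACDEFGHIKL", "a"), seq("MNPQRSTVWY", "b")]
        p = tmp_path / "rt.fasta"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(s.id, s.residues) for s in back] == \
               [(s.id, s.residues) for s in seqs]

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            Sequence(id="bad", residues="ACDB1")


class TestLocalAlign:
    def test_identity_alignment(self):
        aln = local_align(seq("ACDE", "a"), seq("ACDE", "b"))
        assert aln.score == 4.0
        assert aln.aligned_a == aln.aligned_b == "ACDE"

    def test_local_region_with_offset(self):
        aln = local_align(seq("KVIIT", "a"), seq("GGKVIITGG", "b"))
        assert aln.score == 5.0
        assert aln.start_b == 2 and aln.end_b == 7

    def test_no_positive_alignment_is_empty(self):
        aln = local_align(seq("AAAA", "a"), seq("CCCC", "b"))
        assert aln.score == 0.0 and aln.is_empty

    def test_x_never_matches(self):
        aln = local_align(seq("AXA", "a"), seq("AXA", "b"))
        # two A matches; the X column scores 0
        assert aln.score == 2.0

    def test_score_matches_gotoh_oracle(self, rng):
        """Biopython-backed scores equal the independent Gotoh DP."""
        alphabet = "ACDE"
        for _ in range(200):
            a = "".join(rng.choice(list(alphabet), size=rng.integers(1, 9)))
            b = "".join(rng.choice(list(alphabet), size=rng.integers(1, 9)))
            got = local_align(seq(a, "a"), seq(b, "b")).score
            assert got == pytest.approx(oracles.gotoh_local_score(a, b))

    def test_oracle_agrees_with_full_enumeration(self, rng):
        """The DP oracle itself equals brute-force path enumeration."""
        alphabet = "ACDE"
        for _ in range(25):
            a = "".join(rng.choice(list(alphabet), size=rng.integers(1, 5)))
            b = "".join(rng.choice(list(alphabet), size=rng.integers(1, 5)))
            assert oracles.gotoh_local_score(a, b) == \
                pytest.approx(oracles.enumerate_local_score(a, b))


class TestPairwiseIdentity:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACDE", "ACDE", 1.0),
        ("ACDE", "ACDF", 0.75),
        ("AC-E", "ACDE", 1.0),          # gap column dropped from denominator
    ])
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_no_overlap_errors(self):
        with pytest.raises(ValueError):
            pairwise_identity("A---", "-CCC")

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACDE", min_size=1, max_size=12),
           st.text(alphabet="ACDE", min_size=1, max_size=12))
    def test_symmetric_and_reflexive(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert pairwise_identity(a, b) == pairwise_identity(b, a)
        assert pairwise_identity(a, a) == 1.0


class TestIdentityMatrix:
    def test_identical_pair(self):
        m = identity_matrix([seq("ACDEFG", "a"), seq("ACDEFG", "b")])
        assert np.allclose(m.values, 1.0)

    def test_cells_match_pairwise_identity(self):
        seqs = [seq("ACDEFGHIKL", "a"), seq("ACDEFGHIKV", "b"),
                seq("MNPQRSTVWY", "c")]
        m = identity_matrix(seqs)
        for i in range(3):
            for j in range(i + 1, 3):
                aln = local_align(seqs[i], seqs[j])
                expected = 0.0 if aln.is_empty else pairwise_identity(aln)
                assert m.values[i, j] == pytest.approx(expected)

    def test_single_sequence_errors(self):
        with pytest.raises(ValueError):
            identity_matrix([seq("ACDE", "a")])

    def test_msa_rows(self):
        m = identity_matrix([("a", "ACDE"), ("b", "ACDF")], aligned=True)
        assert m.values[0, 1] == pytest.approx(0.75)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            IdentityMatrix(ids=["a", "b"],
                           values=np.array([[1.0, 0.5], [0.4, 1.0]]))


class TestClusterByIdentity:
    def _matrix(self, vals, ids=None):
        vals = np.asarray(vals, dtype=float)
        return IdentityMatrix(ids=ids or [f"s{i}" for i in range(len(vals))],
                              values=vals)

    def test_all_similar_single_cluster(self):
        m = self._matrix([[1.0, 0.9, 0.92], [0.9, 1.0, 0.95],
                          [0.92, 0.95, 1.0]])
        cs = cluster_by_identity(m, 0.78)
        assert len(cs.clusters) == 1

    def test_two_blocks(self):
        m = self._matrix([[1.0, 1.0, 0.1, 0.1], [1.0, 1.0, 0.1, 0.1],
                          [0.1, 0.1, 1.0, 1.0], [0.1, 0.1, 1.0, 1.0]])
        cs = cluster_by_identity(m, 0.78)
        assert sorted(len(c) for c in cs.clusters) == [2, 2]

    def test_threshold_one_gives_singletons(self):
        m = self._matrix([[1.0, 0.99, 0.98], [0.99, 1.0, 0.97],
                          [0.98, 0.97, 1.0]])
        cs = cluster_by_identity(m, 1.0)
        assert sorted(len(c) for c in cs.clusters) == [1, 1, 1]

    def test_boundary_identity_merges(self):
        m = self._matrix([[1.0, 0.78], [0.78, 1.0]])
        cs = cluster_by_identity(m, 0.78)
        assert len(cs.clusters) == 1

    def test_invariant_on_random_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 10))
            v = rng.uniform(0, 1, size=(n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            cs = cluster_by_identity(self._matrix(v), 0.78)
            ids = cs.clusters
            assert sorted(m for c in ids for m in c) == \
                sorted(f"s{i}" for i in range(n))
            for c in ids:
                members = sorted(c)
                for i, a in enumerate(members):
                    for b in members[i + 1:]:
                        ia, ib = int(a[1:]), int(b[1:])
                        assert v[ia, ib] >= 0.78 - 1e-12


class TestIdentityStats:
    def test_pair(self):
        m = IdentityMatrix(ids=["a", "b"],
                           values=np.array([[1.0, 0.5], [0.5, 1.0]]))
        s = identity_stats(m)
        assert s["mean"] == s["median"] == pytest.approx(0.5)

    def test_three_by_three(self):
        v = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        s = identity_stats(IdentityMatrix(ids=list("abc"), values=v))
        assert s["mean"] == pytest.approx(0.4)
        assert s["median"] == pytest.approx(0.4)

    def test_permutation_invariant(self, rng):
        n = 6
        v = rng.uniform(0, 1, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        base = identity_stats(IdentityMatrix(ids=[str(i) for i in range(n)],
                                             values=v))
        perm = rng.permutation(n)
        vp = v[np.ix_(perm, perm)]
        permuted = identity_stats(
            IdentityMatrix(ids=[str(i) for i in perm], values=vp))
        assert permuted["mean"] == pytest.approx(base["mean"])
        assert permuted["median"] == pytest.approx(base["median"])

    def test_single_id_errors(self):
        with pytest.raises(ValueError):
            identity_stats(IdentityMatrix(ids=["a"], values=np.array([[1.0]])))
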