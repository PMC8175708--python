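"""Fingerprint kernels, Smith–Waterman scores, PSD repair."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from kronbind.io import CompoundRecord, ProteinRecord
from kronbind.kernels import (
    AlignmentScoring,
    Fingerprint,
    FingerprintSpec,
    KernelMatrix,
    ensure_psd,
    fingerprint,
    protein_kernel,
    qed_fingerprint_specs,
    read_fingerprints_tsv,
    read_kernel_tsv,
    similarity_kernel,
    sw_score,
    write_fingerprints_tsv,
    write_kernel_tsv,
)

ASPIRIN = "CC(=O)Oc1ccccc1C(=O)O"


def fp_from_bits(on_bits, n=64):
    arr = np.zeros(n, dtype=np.uint8)
    arr[list(on_bits)] = 1
    return Fingerprint(arr)


class TestSimilarityKernel:
    def test_tanimoto_worked_example(self):
        a = fp_from_bits({1, 2, 3, 4})
        b = fp_from_bits({3, 4, 5})
        k = similarity_kernel([a, b], "tanimoto")
        assert k.values[0, 1] == pytest.approx(2 / 5)  # 2 shared / 5 union

    def test_dice_worked_example(self):
        a = fp_from_bits({1, 2, 3, 4})
        b = fp_from_bits({3, 4, 5})
        k = similarity_kernel([a, b], "dice")
        assert k.values[0, 1] == pytest.approx(4 / 7)  # 2*2 / (4+3)

    def test_identical_fingerprints_similarity_one(self):
        a = fp_from_bits({0, 7, 13})
        for metric in ("tanimoto", "dice"):
            k = similarity_kernel([a, a], metric)
            assert k.values[0, 1] == pytest.approx(1.0)

    def test_all_zero_fingerprints_convention(self):
        z = fp_from_bits(set())
        k = similarity_kernel([z, z], "tanimoto")
        assert k.values[0, 0] == 1.0
        assert k.values[0, 1] == 0.0

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            similarity_kernel([fp_from_bits({1}, 64), fp_from_bits({1}, 32)])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.sets(st.integers(0, 63), max_size=40),
        st.sets(st.integers(0, 63), max_size=40),
    )
    def test_dice_dominates_tanimoto_entrywise(self, on_a, on_b):
        fps = [fp_from_bits(on_a), fp_from_bits(on_b)]
        t = similarity_kernel(fps, "tanimoto").values
        d = similarity_kernel(fps, "dice").values
        assert np.all(d >= t - 1e-12)
        for k in (t, d):
            assert np.allclose(k, k.T)
            assert np.allclose(np.diag(k), 1.0)


class TestFingerprint:
    def test_smiles_fingerprint_deterministic(self):
        spec = FingerprintSpec()
        c = CompoundRecord("asp", smiles=ASPIRIN)
        f1, f2 = fingerprint(c, spec), fingerprint(c, spec)
        assert np.array_equal(f1.bits, f2.bits)
        assert len(f1) == 1024

    def test_path_fingerprint_differs_from_circular(self):
        c = CompoundRecord("asp", smiles=ASPIRIN)
        circ = fingerprint(c, FingerprintSpec(kind="circular"))
        path = fingerprint(c, FingerprintSpec(kind="path", radius_or_depth=5))
        assert not np.array_equal(circ.bits, path.bits)

    def test_precomputed_passthrough_and_length_check(self):
        bits = np.zeros(1024, dtype=np.uint8)
        bits[3] = 1
        c = CompoundRecord("x", fingerprint=bits)
        assert np.array_equal(fingerprint(c, FingerprintSpec()).bits, bits)
        with pytest.raises(ValueError, match="n_bits"):
            fingerprint(c, FingerprintSpec(n_bits=256))

    def test_unparsable_smiles_names_compound(self):
        c = CompoundRecord("junk", smiles="not_a_molecule((")
        with pytest.raises(ValueError, match="junk"):
            fingerprint(c, FingerprintSpec())

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="power of two"):
            FingerprintSpec(n_bits=1000)
        with pytest.raises(ValueError):
            FingerprintSpec(radius_or_depth=0)

    def test_qed_grid_has_eight_distinct_kernel_recipes(self):
        specs = qed_fingerprint_specs()
        assert len(specs) == 8
        assert len(set(specs)) == 8
        radii = {s.radius_or_depth for s, _ in specs}
        metrics = {m for _, m in specs}
        assert radii == {2, 3} and metrics == {"tanimoto", "dice"}


def naive_sw(a: str, b: str, scoring: AlignmentScoring) -> float:
    """Quadratic Gotoh local-alignment oracle (gap of length L costs
    open + L*extend)."""
    sub = substitution_matrices.load(scoring.substitution_matrix)
    go, ge = scoring.gap_open, scoring.gap_extend
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (moving along b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - ge, H[i, j - 1] - go - ge)
            F[i, j] = max(F[i - 1, j] - ge, H[i - 1, j] - go - ge)
            H[i, j] = max(
                0.0,
                H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]],
                E[i, j],
                F[i, j],
            )
            best = max(best, H[i, j])
    return best


class TestSmithWaterman:
    def test_identical_poly_a_scores_sixteen(self):
        # 4 aligned A/A pairs x BLOSUM62(A, A) = 4
        assert sw_score("AAAA", "AAAA") == 16.0

    def test_dissimilar_residues_score_zero(self):
        # W/A = -3 in BLOSUM62: no positive local alignment exists
        assert sw_score("WWWW", "AAAA") == 0.0

    def test_self_score_equals_diagonal_sum_when_gapless_optimal(self):
        sub = substitution_matrices.load("BLOSUM62")
        seq = "MKTAYIAKQRQISFVK"
        assert sw_score(seq, seq) == sum(sub[ch, ch] for ch in seq)

    def test_agrees_with_quadratic_dp_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        scoring = AlignmentScoring()
        for _ in range(25):
            a = "".join(rng.choice(aa, size=rng.integers(5, 50)))
            b = "".join(rng.choice(aa, size=rng.integers(5, 50)))
            assert sw_score(a, b, scoring) == pytest.approx(naive_sw(a, b, scoring))
            assert sw_score(a, b, scoring) == sw_score(b, a, scoring)

    def test_agrees_with_oracle_under_alternative_gap_penalties(self):
        rng = np.random.default_rng(3)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        scoring = AlignmentScoring(gap_open=5.0, gap_extend=2.0)
        for _ in range(10):
            a = "".join(rng.choice(aa, size=30))
            b = "".join(rng.choice(aa, size=30))
            assert sw_score(a, b, scoring) == pytest.approx(naive_sw(a, b, scoring))

    def test_illegal_residue_position_reported(self):
        with pytest.raises(ValueError, match="position 2"):
            sw_score("MK1T", "MKT")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sw_score("", "MKT")


class TestProteinKernel:
    def _proteins(self, seqs):
        return [ProteinRecord(f"P{i}", s) for i, s in enumerate(seqs)]

    def test_identical_sequences_entry_one(self):
        k = protein_kernel(self._proteins(["MKTAYIAKQR", "MKTAYIAKQR"]))
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_unit_diagonal_and_unit_bound(self):
        rng = np.random.default_rng(5)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = ["".join(rng.choice(aa, size=40)) for _ in range(5)]
        k = protein_kernel(self._proteins(seqs))
        assert np.allclose(np.diag(k.values), 1.0)
        assert np.all(k.values >= 0) and np.all(k.values <= 1)

    def test_unrelated_random_sequences_near_zero(self):
        rng = np.random.default_rng(9)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        a = "".join(rng.choice(aa, size=60))
        b = "".join(rng.choice(aa, size=60))
        k = protein_kernel(self._proteins([a, b]))
        assert k.values[0, 1] < 0.3

    def test_duplicated_sequences_give_identical_rows(self):
        rng = np.random.default_rng(2)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        s = "".join(rng.choice(aa, size=30))
        t = "".join(rng.choice(aa, size=30))
        k = protein_kernel(self._proteins([s, t, s]))
        assert np.allclose(k.values[0], k.values[2])


class TestEnsurePsd:
    def test_indefinite_two_by_two_repaired(self):
        # eigenvalues of [[1, 1.2], [1.2, 1]] are -0.2 and 2.2
        k = KernelMatrix(("a", "b"), np.array([[1.0, 1.2], [1.2, 1.0]]))
        assert k.min_eigenvalue() == pytest.approx(-0.2)
        fixed = ensure_psd(k)
        assert fixed.min_eigenvalue() >= -1e-8
        assert np.allclose(np.diag(fixed.values), 1.0)

    def test_psd_input_returned_unchanged(self):
        k = KernelMatrix(("a", "b"), np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert ensure_psd(k) is k

    def test_repair_preserves_offdiagonal_ordering(self):
        vals = np.array(
            [[1.0, 0.95, 0.2], [0.95, 1.0, 0.9], [0.2, 0.9, 1.0]]
        )
        k = KernelMatrix(("a", "b", "c"), vals - 0.3 * np.eye(3) * 0)  # keep as-is
        fixed = ensure_psd(KernelMatrix(("a", "b", "c"), vals))
        orig_order = np.argsort([vals[0, 1], vals[0, 2], vals[1, 2]])
        new = fixed.values
        new_order = np.argsort([new[0, 1], new[0, 2], new[1, 2]])
        assert np.array_equal(orig_order, new_order)


class TestKernelMatrix:
    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            KernelMatrix(("a", "b"), np.array([[1.0, 0.2], [0.4, 1.0]]))

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        B = rng.normal(size=(4, 4))
        K = B @ B.T
        d = np.sqrt(np.diag(K))
        k = KernelMatrix(tuple("wxyz"), K / np.outer(d, d))
        path = tmp_path / "k.tsv"
        write_kernel_tsv(k, path)
        back = read_kernel_tsv(path)
        assert back.ids == k.ids
        assert np.allclose(back.values, k.values, atol=1e-11)

    def test_fingerprint_tsv_round_trip(self, tmp_path):
        fps = [fp_from_bits({1, 5, 9}, 64), fp_from_bits({0, 63}, 64)]
        path = tmp_path / "fp.tsv"
        write_fingerprints_tsv(fps, ["a", "b"], path)
        back, ids = read_fingerprints_tsv(path, 64)
        assert ids == ["a", "b"]
        for f, g in zip(fps, back):
            assert np.array_equal(f.bits, g.bits)
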