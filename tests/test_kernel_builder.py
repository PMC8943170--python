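"""Substitution kernels, post-processing chain, diagnostics, baselines."""

import numpy as np
import pytest

import edkernel as ek
from edkernel.edit_distance import DistanceMatrix
from edkernel.errors import ParameterError
from edkernel.kernel_builder import (
    baseline_kernel,
    center,
    cosine_normalize,
    is_psd,
    kernel_alignment,
    median_heuristic_sigma,
    spectral_modify,
    substitution_kernel,
)


def _ids(n):
    return tuple(f"i{k}" for k in range(n))


def _km(V, ids=None):
    V = np.asarray(V, dtype=float)
    return ek.KernelMatrix(V, ids or _ids(V.shape[0]))


class TestSubstitutionKernel:
    def test_diagonal_equals_distance_to_origin(self, small_ds, worked):
        *_, x0, _ = worked
        K = ek.edit_substitution_kernel(small_ds, x0)
        d0 = ek.distances_to_reference(small_ds, x0)
        assert np.allclose(np.diag(K.values), d0)
        assert K.provenance["zero_vector_id"] == "w0"
        assert K.provenance["distance_variant"] == "k_ed1"

    def test_worked_arithmetic(self):
        # two sequences with d(i,x0)=3, d(j,x0)=2, d(i,j)=2 -> K(i,j)=1.5
        D = DistanceMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), ("i", "j"), "k_ed1")
        K = substitution_kernel(D, np.array([3.0, 2.0]), "origin")
        assert K.values[0, 1] == pytest.approx(1.5)
        assert K.values[0, 0] == 3.0 and K.values[1, 1] == 2.0

    def test_worked_triple_from_fixture(self, worked):
        x, xp, x0, exp = worked
        ds = ek.LabeledDataset((x, xp))
        K = ek.edit_substitution_kernel(ds, x0)
        assert K.values[0, 1] == pytest.approx(exp["k1"])

    def test_member_origin_rejected_unless_flagged(self, small_ds):
        D = ek.pairwise_distances(small_ds)
        d0 = D.values[:, 0]
        with pytest.raises(ParameterError, match="member"):
            substitution_kernel(D, d0, small_ds.ids[0])
        K = substitution_kernel(D, d0, small_ds.ids[0], x0_in_pool=True)
        assert K.values[0, 0] == 0.0  # the origin scores 0 against itself

    def test_one_symbol_alphabet_line_embedding(self, rng):
        """Single-symbol sequences embed on a length line: the kernel takes
        the closed form 1/2(|a|+|b|-|a-b|) with a = l_i - l_0, b = l_j - l_0
        (min(|a|,|b|) for same-sign a, b, else 0) and is PSD."""
        for _ in range(10):
            lens = rng.integers(1, 30, size=8)
            l0 = int(rng.integers(1, 30))
            ds = ek.LabeledDataset(tuple(
                ek.SymbolSequence(f"s{k}", ("A",) * int(l),) for k, l in enumerate(lens)
            ))
            x0 = ek.SymbolSequence("origin", ("A",) * l0)
            K = ek.edit_substitution_kernel(ds, x0)
            a = lens[:, None] - l0
            b = lens[None, :] - l0
            closed = 0.5 * (np.abs(a) + np.abs(b) - np.abs(a - b))
            assert np.allclose(K.values, closed)
            assert is_psd(K).is_psd

    def test_id_mismatch_rejected(self, small_ds):
        D = ek.pairwise_distances(small_ds)
        with pytest.raises(ParameterError):
            substitution_kernel(D, np.zeros(3), "x0")


class TestPostProcessing:
    def test_cosine_normalize_unit_diagonal(self):
        K = cosine_normalize(_km([[4.0, 2.0], [2.0, 1.0]]))
        assert np.allclose(K.values, 1.0)
        assert K.provenance["postprocessing"][-1] == "normalize"

    def test_cosine_normalize_zero_diagonal_guard(self):
        K = cosine_normalize(_km([[0.0, 1.0], [1.0, 2.0]]))
        assert np.allclose(K.values[0], 0.0) and np.allclose(K.values[:, 0], 0.0)
        assert K.values[1, 1] == 1.0

    def test_center_constant_matrix_to_zero(self):
        K = center(_km(np.full((4, 4), 7.0)))
        assert np.allclose(K.values, 0.0)

    def test_center_hand_example_and_idempotence(self):
        K = center(_km(np.eye(2)))
        assert np.allclose(K.values, [[0.5, -0.5], [-0.5, 0.5]])
        assert np.allclose(center(K).values, K.values)

    def test_center_zeroes_row_and_column_sums(self, rng):
        V = rng.normal(size=(6, 6))
        K = center(_km(V + V.T))
        assert np.all(np.abs(K.values.sum(axis=0)) < 1e-8)
        assert np.all(np.abs(K.values.sum(axis=1)) < 1e-8)

    @pytest.mark.parametrize("mode", ["clip", "shift", "flip", "square"])
    def test_spectral_modes_produce_psd(self, mode, rng):
        for _ in range(10):
            V = rng.normal(size=(7, 7))
            K = spectral_modify(_km(V + V.T), mode)
            rep = is_psd(K)
            assert rep.is_psd, f"{mode}: min eig {rep.min_eigenvalue}"
            assert K.provenance["postprocessing"][-1] == mode

    def test_clip_and_flip_hand_reconstructions(self):
        # [[0,2],[2,0]] has eigenvalues +/-2 with eigenvectors (1,1)/sqrt2, (1,-1)/sqrt2
        K = _km([[0.0, 2.0], [2.0, 0.0]])
        assert np.allclose(spectral_modify(K, "clip").values, [[1.0, 1.0], [1.0, 1.0]])
        assert np.allclose(spectral_modify(K, "flip").values, [[2.0, 0.0], [0.0, 2.0]])
        shifted = spectral_modify(K, "shift")
        assert np.allclose(shifted.values, [[2.0, 2.0], [2.0, 2.0]])
        assert np.allclose(spectral_modify(K, "square").values, [[4.0, 0.0], [0.0, 4.0]])

    def test_clip_leaves_psd_kernel_unchanged(self, rng):
        A = rng.normal(size=(5, 5))
        K = _km(A @ A.T)
        assert np.allclose(spectral_modify(K, "clip").values, K.values, atol=1e-10)

    def test_chain_preserves_symmetry(self, small_ds, worked):
        *_, x0, _ = worked
        K = ek.edit_substitution_kernel(small_ds, x0, post=("clip", "normalize", "center"))
        assert np.allclose(K.values, K.values.T, atol=1e-10)
        assert K.provenance["postprocessing"] == ["raw", "clip", "normalize", "center"]

    def test_unknown_chain_step(self, separable_kernel):
        K, _ = separable_kernel
        with pytest.raises(ParameterError):
            ek.apply_chain(K, ("sparkle",))


class TestDiagnostics:
    def test_is_psd_examples(self):
        assert is_psd(_km(np.eye(3))).is_psd
        rep = is_psd(_km([[0.0, 2.0], [2.0, 0.0]]))
        assert not rep.is_psd
        assert rep.min_eigenvalue == pytest.approx(-2.0)
        assert rep.negative_mass_fraction == pytest.approx(0.5)

    def test_alignment_perfect_and_orthogonal(self):
        y = np.array([1, 1, -1, -1])
        K = _km(np.outer(y, y).astype(float))
        assert kernel_alignment(K, y) == pytest.approx(1.0)
        # identity vs yy^T at n=4: 4 / (2 * 4)
        assert kernel_alignment(_km(np.eye(4)), y) == pytest.approx(0.5)
        # K[0,1]=+1 and K[2,3]=-1 contribute +2 and -2 to <K, yy^T>
        orth = np.zeros((4, 4))
        orth[0, 1] = orth[1, 0] = 1.0
        orth[2, 3] = orth[3, 2] = -1.0
        assert kernel_alignment(_km(orth), y) == pytest.approx(0.0)

    def test_alignment_scale_invariance(self, rng):
        y = np.array([1, -1, 1, -1, 1])
        V = rng.normal(size=(5, 5))
        K = _km(V + V.T)
        assert kernel_alignment(K, y) == pytest.approx(
            kernel_alignment(_km(7.3 * K.values), y))

    def test_alignment_single_class_rejected(self):
        with pytest.raises(ParameterError):
            kernel_alignment(_km(np.eye(3)), np.array([1, 1, 1]))


class TestBaselineKernels:
    def test_rbf_identical_rows_give_one(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        K = baseline_kernel(X, "rbf", sigma=1.0)
        assert K.values[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(K.values), 1.0)

    def test_linear_one_hot_is_identity(self):
        K = baseline_kernel(np.eye(4), "linear")
        assert np.array_equal(K.values, np.eye(4))

    def test_poly_closed_form(self):
        X = np.array([[1.0], [2.0]])
        K = baseline_kernel(X, "poly", c=1.0, degree=3)
        assert K.values[0, 1] == pytest.approx((1 * 2 + 1) ** 3)

    def test_laplace_closed_form_at_sigma(self):
        X = np.array([[0.0], [2.0]])
        K = baseline_kernel(X, "laplace", sigma=2.0)
        assert K.values[0, 1] == pytest.approx(np.exp(-1.0))

    def test_laplace_equals_exp_rbf_at_doubled_sigma(self, rng):
        X = rng.normal(size=(6, 3))
        K_lap = baseline_kernel(X, "laplace", sigma=3.0)
        K_exp = baseline_kernel(X, "exp_rbf", sigma=1.5)
        assert np.allclose(K_lap.values, K_exp.values)

    def test_all_kinds_psd(self, rng):
        X = rng.normal(size=(8, 4))
        for kind in ("linear", "poly", "rbf", "exp_rbf", "laplace"):
            assert is_psd(baseline_kernel(X, kind), tol=1e-6).is_psd, kind

    def test_bad_sigma_rejected(self):
        with pytest.raises(ParameterError):
            baseline_kernel(np.eye(3), "rbf", sigma=0.0)

    def test_median_heuristic(self):
        X = np.array([[0.0], [1.0], [2.0]])
        assert median_heuristic_sigma(X) == 1.0
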