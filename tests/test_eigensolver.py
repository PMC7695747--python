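import numpy as np
import pytest

from qae import (
    CheckpointError,
    EncodingSpec,
    Eigenpair,
    LambdaBracket,
    SolverConfig,
    SpectrumConfig,
    SpectrumSpec,
    ValidationError,
    bisect_lambda,
    classify_solution,
    deflate,
    generate_matrix_with_spectrum,
    initial_bracket,
    load_checkpoint,
    rayleigh_quotient,
    save_checkpoint,
    solve_ground,
    solve_spectrum,
)
from qae.eigensolver import CheckpointState, matrix_fingerprint

from conftest import make_random_symmetric

EXACT = SolverConfig(mode="exact")
TABU = SolverConfig(mode="tabu", seed=0)
FAST = SpectrumConfig(lambda_tol=1e-3)


class TestRayleighQuotient:
    def test_exact_eigenvector(self):
        assert rayleigh_quotient([[0.0, 1.0], [1.0, 0.0]], [1.0, -1.0]) == -1.0

    def test_basis_vector_on_diagonal_matrix(self):
        assert rayleigh_quotient(np.diag([-1.0, 2.0]), [1.0, 0.0]) == -1.0

    def test_scale_invariance(self):
        A = make_random_symmetric(3, 4)
        v = np.array([0.3, -0.1, 0.7, 0.2])
        assert rayleigh_quotient(A, v) == pytest.approx(rayleigh_quotient(A, 3 * v),
                                                        rel=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            rayleigh_quotient(np.eye(2), [0.0, 0.0])


class TestClassifySolution:
    def test_null_vector_is_trivial(self):
        assert classify_solution(np.zeros(5), EncodingSpec(K=10)) == "trivial"

    def test_clearly_nonzero_is_nontrivial(self):
        v = np.zeros(5)
        v[0] = 0.5
        assert classify_solution(v, EncodingSpec(K=10)) == "nontrivial"

    def test_single_stray_low_bit_counts_as_trivial(self):
        spec = EncodingSpec(K=10)
        v = np.zeros(4)
        v[2] = spec.delta  # one lowest-weight bit of solver noise
        assert classify_solution(v, spec) == "trivial"

    def test_threshold_is_configurable(self):
        v = np.array([0.01, 0.0])
        assert classify_solution(v, EncodingSpec(K=10), eta=0.5) == "trivial"
        assert classify_solution(v, EncodingSpec(K=10), eta=0.001) == "nontrivial"


class TestLambdaBracketing:
    def test_bracket_contains_the_phase_transition(self):
        # diag(-1, 2): nontrivial below lambda=1, trivial above
        br = initial_bracket(np.diag([-1.0, 2.0]), EncodingSpec(K=6), EXACT, FAST)
        assert br.lo < 1.0 < br.hi
        assert (br.lo, br.hi) == (-2.0, 2.0)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            initial_bracket(np.zeros((2, 2)), EncodingSpec(K=4), EXACT, FAST)

    def test_bisection_converges_to_minus_lambda_min(self):
        A = np.diag([-1.0, 2.0])
        spec = EncodingSpec(K=8)
        records = []
        br = initial_bracket(A, spec, EXACT, FAST, records=records)
        lam_opt, records = bisect_lambda(A, br, spec, EXACT, FAST, records=records)
        assert lam_opt == pytest.approx(1.0, abs=FAST.lambda_tol)

    def test_narrow_bracket_returns_without_solving(self):
        A = np.diag([-1.0, 2.0])
        br = LambdaBracket(lo=0.9999, hi=1.0)
        records = []
        lam_opt, _ = bisect_lambda(A, br, EncodingSpec(K=6), EXACT, FAST,
                                   records=records)
        assert records == []
        assert lam_opt == br.midpoint


class TestSolveGround:
    def test_representable_eigenvector_is_exact(self):
        pair = solve_ground(np.diag([-1.0, 2.0]), EncodingSpec(K=6), EXACT, FAST)
        assert pair.value == -1.0
        assert abs(np.linalg.norm(pair.vector) - 1.0) <= 1e-12

    def test_direction_exact_after_normalization(self):
        # any v = (a, -a) normalizes to the exact eigenvector of [[0,1],[1,0]]
        pair = solve_ground(np.array([[0.0, 1.0], [1.0, 0.0]]),
                            EncodingSpec(K=10), TABU, FAST)
        assert pair.value == pytest.approx(-1.0, abs=1e-12)

    def test_close_to_dense_oracle_on_random_matrix(self):
        A = make_random_symmetric(17, 3)
        lam_min = np.linalg.eigvalsh(A).min()
        pair = solve_ground(A, EncodingSpec(K=5), EXACT, FAST)
        assert lam_min - 1e-9 <= pair.value <= lam_min + 0.05

    def test_variational_bound_across_seeds(self):
        for seed in range(5):
            A = make_random_symmetric(seed, 4)
            pair = solve_ground(A, EncodingSpec(K=4), TABU, FAST)
            assert pair.value >= np.linalg.eigvalsh(A).min() - 1e-9

    def test_value_recomputable_from_vector(self):
        A = make_random_symmetric(23, 3)
        pair = solve_ground(A, EncodingSpec(K=5), EXACT, FAST)
        assert pair.value == pytest.approx(
            rayleigh_quotient(A, pair.vector), rel=1e-10)


class TestDeflate:
    def test_brauer_on_exact_basis_eigenvector(self):
        out = deflate(np.diag([1.0, 2.0]), Eigenpair(1.0, np.array([1.0, 0.0])), 10.0)
        np.testing.assert_array_equal(out, np.diag([11.0, 2.0]))

    def test_only_target_eigenvalue_moves(self):
        A = make_random_symmetric(31, 4)
        vals, vecs = np.linalg.eigh(A)
        out = deflate(A, Eigenpair(vals[0], vecs[:, 0]), 1.0)
        expected = np.sort(np.concatenate([[vals[0] + 1.0], vals[1:]]))
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(out)), expected,
                                   atol=1e-9)

    def test_zero_shift_is_identity(self):
        A = make_random_symmetric(5, 3)
        v = np.linalg.eigh(A)[1][:, 0]
        np.testing.assert_array_equal(deflate(A, Eigenpair(0.0, v), 0.0), A)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValidationError):
            deflate(np.eye(2), Eigenpair(1.0, np.array([1.0, 1.0])), 1.0)


class TestSolveSpectrum:
    def test_diagonal_matrix_recovered_exactly(self):
        pairs = solve_spectrum(np.diag([1.0, 2.0, 3.0]), EncodingSpec(K=6), TABU,
                               SpectrumConfig(n_states=3, lambda_tol=1e-3))
        np.testing.assert_allclose([p.value for p in pairs], [1.0, 2.0, 3.0],
                                   atol=1e-9)

    def test_single_state_matches_solve_ground(self):
        A = make_random_symmetric(13, 3)
        spec = EncodingSpec(K=5)
        one = solve_spectrum(A, spec, EXACT, SpectrumConfig(n_states=1,
                                                            lambda_tol=1e-3))
        assert len(one) == 1
        assert one[0].value == solve_ground(A, spec, EXACT, FAST).value

    def test_too_many_states_rejected(self):
        with pytest.raises(ValidationError):
            solve_spectrum(np.eye(2), EncodingSpec(K=4), EXACT,
                           SpectrumConfig(n_states=3))

    def test_values_close_to_dense_oracle(self):
        ev = [-2.0, -1.0, 0.5, 1.1, 1.9, 2.6]
        A = generate_matrix_with_spectrum(SpectrumSpec(eigenvalues=ev, seed=3))
        pairs = solve_spectrum(A, EncodingSpec(K=8), TABU,
                               SpectrumConfig(n_states=3, lambda_tol=1e-3))
        for pair, truth in zip(pairs, ev):
            assert abs(pair.value - truth) <= 0.05


class TestCheckpoint:
    def _run(self, A, checkpoint=None, stop_after=None):
        return solve_spectrum(A, EncodingSpec(K=6), TABU,
                              SpectrumConfig(n_states=3, lambda_tol=1e-3),
                              checkpoint_path=checkpoint, stop_after=stop_after)

    def test_save_load_round_trip(self, tmp_path):
        A = make_random_symmetric(7, 4)
        state = CheckpointState(fingerprint=matrix_fingerprint(A),
                                pairs=[Eigenpair(1.5, np.array([1.0, 0, 0, 0]),
                                                 lambda_opt=-1.5)],
                                mus=[8.0], next_state=1,
                                config_echo={"seed": 0})
        p = tmp_path / "ck.json"
        save_checkpoint(state, p)
        back = load_checkpoint(p, A)
        assert back.fingerprint == state.fingerprint
        assert back.next_state == 1
        assert back.mus == [8.0]
        assert back.pairs[0].value == 1.5
        np.testing.assert_array_equal(back.pairs[0].vector, state.pairs[0].vector)

    def test_interrupt_and_resume_is_bitwise_identical(self, tmp_path):
        A = generate_matrix_with_spectrum(
            SpectrumSpec(eigenvalues=(-1.5, -0.3, 0.8, 2.1), seed=9))
        full = self._run(A)
        ck = tmp_path / "ck.json"
        partial = self._run(A, checkpoint=ck, stop_after=1)
        assert len(partial) == 1
        resumed = self._run(A, checkpoint=ck)
        assert [p.value for p in resumed] == [p.value for p in full]
        for a, b in zip(resumed, full):
            np.testing.assert_array_equal(a.vector, b.vector)

    def test_fingerprint_mismatch_refuses_resume(self, tmp_path):
        A = make_random_symmetric(7, 4)
        B = make_random_symmetric(8, 4)
        ck = tmp_path / "ck.json"
        self._run(A, checkpoint=ck, stop_after=1)
        with pytest.raises(CheckpointError):
            load_checkpoint(ck, B)
        with pytest.raises(CheckpointError):
            self._run(B, checkpoint=ck)
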