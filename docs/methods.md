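# Methods

This note documents the model implemented by `qae`, the parameters that
matter, the numerical choices made where the design was open, what the
synthetic test matrices do and do not exercise, and known limitations.

## Problem and mapping

Given a real symmetric `n×n` matrix `A`, the smallest eigenvalue is the
minimum of the Rayleigh–Ritz quotient `R_A(v) = (v, Av)/(v, v)`. `qae`
minimizes the penalized objective

    F(v) = (v, Av) + λ (v, v)

over vectors whose elements live on a fixed-point grid: element `a` is
represented by `K` bits with weights `2^(i−K)` (`i = 1..K`) and offset −1,

    v_a = −1 + Σ_i 2^(i−K) q_i^a ,

so the representable values are `{−1 + kΔ : k = 0..2^K−1}` with step
`Δ = 2^(1−K)`, covering `[−1, 1−Δ]`. The highest-weight bit (weight 1) plays
the role of a sign bit: `v_a < 0` exactly when it is 0. Two properties of
this offset (excess) encoding are load-bearing:

* it is **affine** in the bits, so `F` expands exactly into a quadratic
  binary polynomial (a QUBO) — no higher-order term reduction is needed; and
* an `n×n` matrix maps to exactly `m = nK` binary variables.

Nearest-point encoding has round-trip error at most `Δ/2 = 2^(−K)`; exact
half-step ties round toward zero (deterministic, norm-conservative). `K = 10`
therefore gives ~10⁻³ elementwise resolution, and in practice the eigenvalue
error is far smaller because the reported value is the Rayleigh quotient of
the *normalized* decoded vector: for a vector aligned with an eigenvector the
first-order error term vanishes and the error is quadratic in the
quantization noise.

The expansion writes `B = A + λI`, doubles all `i < j` bit-pair terms into an
upper-triangular coefficient matrix, folds the `q² = q` squares and the
offset cross-terms into the diagonal, and tracks the leftover additive
constant (`Σ_ab B_ab`, plus the λ dropped when the normalization constraint
`λ(‖v‖−1)²` is reduced to first power) in `QuboProblem.constant`. Tests
verify the identity `qubo_energy(x) + constant = F(decode(x))` to 10⁻¹⁰
relative on random triples; hardware-style solvers ignore the constant.

## The λ search

The QUBO minimum is the null vector for large positive λ and nontrivial for
large negative λ; the informative λ sits at the phase transition, ideally at
`−λ_min(A)`. The search:

1. **Bracketing.** Start at `(−g, +g)` with `g = max|A_ab|`; while the left
   end's solution is trivial double it, likewise (in the other direction) for
   a nontrivial right end; at most 60 doublings per end.
2. **Bisection.** Solve at the midpoint, move the end of matching type,
   repeat. Every nontrivial solution is stored with its normalized
   expectation value `(v, Av)`.
3. **Stopping.** Three criteria: bracket width below `lambda_tol` (default
   10⁻⁶), an iteration cap `max_bisections` (default 60, mandatory — a noisy
   solver can keep the other criteria from ever triggering), and optionally a
   tolerance `tol_R` on the change between consecutive stored expectation
   values.

`tol_R` is **disabled by default** (0). Far from the transition the QUBO
minimizer may combine several descent directions; the resulting expectation
value can plateau at a level unrelated to any eigenvalue, and two equal
consecutive values satisfy any positive tolerance. With the criterion armed,
bisection can stop at such a plateau before reaching the transition
(observed on deflated diagonal matrices); with it disabled the cost is
bounded and small (≤ `max_bisections` solves).

The returned eigenpair is the stored record with the smallest `(v, Av)`,
drawn from **all** solves (bracketing included), and `lambda_opt` is the
final bracket midpoint.

**Trivial-solution test.** A solution counts as trivial when
`‖v‖₂ ≤ max(2Δ, 1/8)`. The `Δ`-scaled part tolerates stray low-weight bits;
the 1/8 floor handles a subtler failure: just above the transition,
heuristic minimizers often return near-null vectors a few grid steps long
whose `F` marginally beats the exact null code. Such artifacts have norm
`O(Δ)` while genuine solutions have norm `O(1)`; classifying the artifacts
as nontrivial would steer the bisection past the transition. The threshold
is configurable (`SpectrumConfig.trivial_eta`).

## Excited states

After each state, the matrix is deflated with the Brauer shift
`A ← A + μ (v ⊗ v)` using the just-found unit vector, and the ground-state
search repeats; every reported value is re-evaluated against the original
matrix. All states use the **same** shift `μ = mu_multiplier · max|A|` of
the *original* matrix (default multiplier 16; 8, 4 or 2 behave essentially
the same). Recomputing μ from the deflated matrix would compound the shifts
geometrically (16× per state) and bury the remaining ~O(1) spectral gaps
under the penalty scale, which heuristic solvers cannot resolve. Because the
deflating vectors are quantized approximations, each deflation injects noise
of order `μ·(v̂·u_j)²` into the remaining spectrum, so later states are
systematically less precise than the ground state.

## QUBO backends

All backends satisfy one contract (`QuboProblem → SolutionRecord`) and are
deterministic for a fixed seed — deliberately unlike the decomposition tools
they emulate, whose run-to-run fluctuation motivated this requirement. An
externally supplied sampler (e.g. annealing hardware) can be injected as a
callable; its output is validated (length, binary values) before use.

* **Exact enumeration** (`m ≤ 26`): vectorized sweep over all bitstrings;
  ties break toward the lexicographically smallest string. The testing
  oracle.
* **Tabu search**: multi-start single-bit-flip search with per-variable
  tenure `max(8, m/10)`, aspiration (a tabu move is allowed if it beats the
  start's incumbent), O(m) delta maintenance via cached row sums, and a
  budget of 40 consecutive non-improving moves per start. 20 independent
  starts by default: the first is the all-zeros string, the second an
  optional warm start, the rest uniform random. On 16-variable random QUBOs
  the defaults reproduce the exact optimum essentially always; 20 starts
  were chosen because the 64-variable deflated-matrix QUBOs of the
  excited-state workflow need the extra diversification.
* **subQUBO decomposition** (for `m` beyond one solver call): repeatedly
  select a block (half highest-|flip-delta| variables, half random — the
  selection heuristic is an open design point in the emulated tools), clamp
  the rest (their contribution folds exactly into the block's linear terms
  and a constant; property-tested), minimize the block with the inner
  solver, accept only non-increasing total energy, then greedily refine.
  Defaults: block 64, 50 repeats.

**Warm starts.** Within one λ search, successive QUBOs differ only in λ, so
each heuristic solve receives the previous nontrivial solution as an extra
start. This costs nothing, preserves determinism, and substantially improves
the quality of the recorded solutions near the transition, where accuracy is
decided.

## Checkpoint/restart

Multi-state runs can write a JSON checkpoint after each completed state
(matrix SHA-256 fingerprint, completed eigenpairs, applied shifts, config
echo). Resuming replays the stored deflations on the original matrix and
continues with the same per-solve seeds, so an interrupted run reproduces
the uninterrupted result bit for bit; a fingerprint mismatch refuses to
resume. This exists because long hardware-backed runs fail in practice.

## Synthetic test matrices

`generate_matrix_with_spectrum` builds `QᵀDQ` from a prescribed ascending
spectrum `D` and a seeded random orthogonal `Q` (QR of a standard-normal
draw with sign-fixed R diagonal, unique and reproducible). Ground truth is
known by construction, which is what the validation suite and the acceptance
script run against. These fixtures emulate the *spectral* structure of real
problems (separated or clustered eigenvalues, arbitrary scale) but not the
*sparsity or sign structure* of configuration-interaction Hamiltonians
(diagonally dominant, all-negative diagonals, thresholded sparse storage);
passing tests therefore demonstrate the mapping, the λ search and the
deflation machinery, not chemistry-scale accuracy claims. Eigenvector
degeneracy is exercised only incidentally: with a degenerate eigenvalue any
vector in the eigenspace is accepted, and test spectra are chosen
well-separated.

## Problem sizes and defaults

The shipped validation uses sizes a single core handles in minutes: 3×3
matrices (50 seeds) for the exact-solver oracle study at `K = 3..6`, an 8×8
with separated spectrum for three-state recovery at `K = 8` with Tabu,
16-variable QUBOs (100 seeds) for the Tabu-vs-exact match rate, and a
200-variable QUBO for the decomposition study. Key defaults: `K = 10`
(element resolution 2⁻¹⁰), `lambda_tol = 10⁻⁶`, `max_bisections = 60`,
`mu_multiplier = 16`, block 64, 50 repeats, 20 Tabu reads.

## Known limitations

* Accuracy for state `k` degrades with `k` (deflation noise; see above).
  Occasional third-state errors of ~0.1 on unit-scale spectra remain at
  default solver effort even though the ground state is reliable to ~10⁻³.
* The λ bisection assumes the trivial/nontrivial classification is
  monotone in λ; with very noisy samplers a misclassified end can shrink
  the bracket to the wrong region. The best-record selection (not the final
  λ) limits, but does not remove, the damage.
* Extrapolation-based λ refinement (DIIS-style) is deliberately not
  implemented; bisection only.
* Maximization (largest eigenvalue) is not provided; negate the matrix.
* Dense matrices only; `m = nK` variables and dense QUBO coefficient
  storage put practical desk-scale limits around a few thousand variables.
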