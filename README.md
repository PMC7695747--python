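# qae — a variational eigensolver over binary optimization backends

`qae` computes the lowest few eigenvalues and eigenvectors of a real
symmetric matrix by turning the Rayleigh–Ritz minimization into a Quadratic
Unconstrained Binary Optimization (QUBO) problem — the native problem class
of quantum annealers — and solving it with interchangeable, fully
deterministic classical backends. It is aimed at people studying
annealing-style formulations of linear algebra, in particular the
diagonalization of electronic-structure Hamiltonians (FCI/CASSCF matrices in
a Slater-determinant basis), without requiring access to annealing hardware:
any external sampler can be plugged in through a one-function contract.

## The method

The smallest eigenvalue of a symmetric `A` is the minimum of the
Rayleigh–Ritz quotient `R_A(v) = (v, Av) / (v, v)`. Each eigenvector element
is encoded with `K` bits in fixed-point form,

    v_a = −1 + Σ_{i=1..K} 2^(i−K) q_i^a,   q_i^a ∈ {0, 1},

which covers `[−1, 1 − Δ]` with step `Δ = 2^(1−K)` and keeps the objective
quadratic in the bits. Because the unconstrained minimum would be the null
vector, the objective carries a normalization penalty with a Lagrange
multiplier λ:

    F(v) = (v, Av) + λ (v, v).

For large positive λ the QUBO minimum is the null vector ("trivial"); for
large negative λ it is not. The useful λ sits at the phase transition between
the regimes (at `−λ_min` in the ideal case). `qae` brackets the transition
starting from `±max|A|` (doubling an end of the wrong type), shrinks the
bracket by bisection while storing every nontrivial solution's normalized
`(v, Av)`, and reports the smallest stored value with its vector. Excited
states follow by Brauer deflation, `A' = A + μ (v₀ ⊗ v₀)` with
`μ = 16·max|A|`, which lifts the found eigenvalue by μ and leaves the rest of
the spectrum unchanged.

Each QUBO is minimized by one of three backends: exact enumeration (`m ≤ 26`
variables), multi-start Tabu search, or a subQUBO block decomposition
(default block 64, 50 repeats) that clamps most variables and solves small
sub-problems with an inner solver — the pattern used by decomposition tools
such as qbsolv, but seeded and reproducible here. See `docs/methods.md` for
parameter details and limitations.

## Worked example

Generate a 4×4 test matrix with a prescribed spectrum and solve for the two
lowest states:

```sh
qae generate -n 4 --eigenvalues "-2,-0.5,0.5,1.5" --seed 7 -o mat4.mtx
qae solve mat4.mtx --states 2 -K 10 --seed 1 --lambda-tol 1e-3
```

The result JSON (abridged) is

```json
{
 "n": 4,
 "eigenpairs": [
  {"value": -1.9999980098120842, "lambda_opt": 2.000426486104757, "...": "..."},
  {"value": -0.4999991800439705, "lambda_opt": 0.4998897759481766, "...": "..."}
 ],
 "reference_values": [-1.9999999999999978, -0.4999999999999982]
}
```

`value` is `(v, Av)` for the normalized decoded vector — here the two lowest
eigenvalues −2 and −0.5, recovered to ~2·10⁻⁶ with 10 bits per element.
`lambda_opt` is the located penalty transition point, which matches
`−λ_min` of the (deflated) matrix, and `reference_values` come from the
dense SciPy diagonalization run alongside for comparison. With
`--units hartree` the eigenvalue errors are also reported in kcal/mol.

Matrices are read from Matrix Market (`.mtx`) or whitespace-delimited dense
text; `qae export-qubo` writes the mapped problem in the qbsolv `.qubo` text
dialect for external samplers.

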