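"""Classical QUBO minimizers behind one sampler contract.

Three interchangeable backends:

* ``solve_exact`` — brute-force enumeration of all 2^m bitstrings (hard cap
  m <= 26); the testing/debugging oracle.
* ``solve_tabu`` — seeded multi-start single-bit-flip Tabu search with
  aspiration; the default workhorse ("classical mode").
* ``solve_subqubo`` — block decomposition for large problems: repeatedly
  clamp all but a small subset of variables, minimize the resulting
  sub-problem with an inner solver (Tabu, exact, or an injected external
  sampler), accept non-increasing moves, and greedily refine.

Unlike the qbsolv tool this emulates, every backend here is deterministic for
a fixed seed, which makes whole eigensolver runs reproducible bit for bit.
An "external sampler" is any callable mapping a QuboProblem to a
SolutionRecord; annealing hardware would plug in through that contract.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .encoding import QuboProblem, qubo_energy
from .errors import SamplerContractError, SolverError, ValidationError

logger = logging.getLogger(__name__)

#: Brute-force enumeration refuses problems larger than this.
EXACT_SOLVER_CAP = 26

__all__ = [
    "EXACT_SOLVER_CAP",
    "SolverConfig",
    "SubquboConfig",
    "SolutionRecord",
    "Sampler",
    "solve_exact",
    "solve_tabu",
    "greedy_refine",
    "select_subqubo_variables",
    "clamp_subproblem",
    "solve_subqubo",
    "minimize_qubo",
]


@dataclass(frozen=True)
class SolverConfig:
    """Backend choice plus the knobs of the Tabu heuristic.

    ``tabu_tenure`` defaults to max(8, m // 10); ``tabu_max_sweeps`` is the
    budget of consecutive non-improving moves before a restart ends;
    ``num_reads`` independent restarts are run and the best kept.
    """

    mode: str = "tabu"  # exact | tabu | subqubo
    seed: int = 0
    tabu_tenure: int | None = None
    tabu_max_sweeps: int = 40
    num_reads: int = 20

    def __post_init__(self):
        if self.mode not in ("exact", "tabu", "subqubo"):
            raise ValidationError(f"unknown solver mode {self.mode!r}")
        if self.num_reads < 1 or self.tabu_max_sweeps < 1:
            raise ValidationError("num_reads and tabu_max_sweeps must be >= 1")


@dataclass(frozen=True)
class SubquboConfig:
    """Block-decomposition parameters: sub-problem size and outer-loop repeats."""

    block_size: int = 64
    repeats: int = 50

    def __post_init__(self):
        if self.block_size < 2:
            raise ValidationError("block_size must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")


@dataclass
class SolutionRecord:
    """A minimizer's answer: bitstring, its energy, and bookkeeping."""

    x: np.ndarray
    energy: float
    backend: str
    n_evaluations: int = 0
    trajectory: list | None = None  # best-so-far per outer repeat (subqubo)

    def to_dict(self) -> dict:
        d = {
            "x": [int(b) for b in self.x],
            "energy": self.energy,
            "backend": self.backend,
            "n_evaluations": self.n_evaluations,
        }
        if self.trajectory is not None:
            d["trajectory"] = list(self.trajectory)
        return d


Sampler = Callable[[QuboProblem], SolutionRecord]
InnerSolver = Union[SolverConfig, Sampler]


def _finish(Q: QuboProblem, x: np.ndarray, backend: str, evals: int,
            trajectory=None) -> SolutionRecord:
    """Package a result, recomputing the energy from x (bookkeeping invariant)."""
    x = np.asarray(x, dtype=np.int8)
    return SolutionRecord(x=x, energy=qubo_energy(Q, x), backend=backend,
                          n_evaluations=evals, trajectory=trajectory)


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------

_CHUNK_BITS = 16


def solve_exact(Q: QuboProblem) -> SolutionRecord:
    """Global minimum by enumerating all 2^m bitstrings (m <= 26).

    Ties are broken toward the lexicographically smallest bit sequence
    (x_0 compared first), so the all-zeros string wins a fully degenerate
    problem.
    """
    m = Q.m
    if m > EXACT_SOLVER_CAP:
        raise SolverError(
            f"exact enumeration refused: m={m} exceeds cap {EXACT_SOLVER_CAP}"
        )
    total = 1 << m
    bit_pos = np.arange(m, dtype=np.int64)
    lex_weight = 1 << (m - 1 - bit_pos)  # x_0 is the most significant digit
    best_e = np.inf
    best_key = -1
    best_x = None
    for start in range(0, total, 1 << _CHUNK_BITS):
        idx = np.arange(start, min(start + (1 << _CHUNK_BITS), total), dtype=np.int64)
        X = ((idx[:, None] >> bit_pos) & 1).astype(float)
        energies = ((X @ Q.coeffs) * X).sum(axis=1)  # BLAS-backed x^T Q x
        emin = energies.min()
        ties = np.nonzero(energies == emin)[0]
        keys = (X[ties] @ lex_weight).astype(np.int64)
        k = int(ties[np.argmin(keys)])
        key = int(keys.min())
        if emin < best_e or (emin == best_e and key < best_key):
            best_e, best_key, best_x = emin, key, X[k].astype(np.int8)
    return _finish(Q, best_x, "exact", total)


# ---------------------------------------------------------------------------
# Tabu search
# ---------------------------------------------------------------------------

def _flip_deltas(x, h):
    # energy change of flipping each bit: (1 - 2 x_p) * (d_p + sum_q O_pq x_q)
    return (1.0 - 2.0 * x) * h


def solve_tabu(Q: QuboProblem, config: SolverConfig,
               init=None) -> SolutionRecord:
    """Seeded multi-start single-bit-flip Tabu search.

    Per start: repeatedly take the best admissible flip (recently flipped
    variables are tabu for `tenure` moves unless the move beats the start's
    incumbent best — aspiration), maintaining all m flip deltas in O(m) per
    move through cached row sums. A start ends after ``tabu_max_sweeps``
    consecutive non-improving moves. The first start is the all-zeros string,
    the second the optional warm start ``init``, the rest uniform random; the
    best over ``num_reads`` starts wins.
    """
    m = Q.m
    d = Q.linear()
    O = Q.symmetric_offdiag()
    tenure = config.tabu_tenure if config.tabu_tenure is not None else max(8, m // 10)
    rng = np.random.default_rng(config.seed)
    hard_cap = 1000 + 50 * m  # safety net per start
    best_e = np.inf
    best_x = None
    evals = 0
    for read in range(config.num_reads):
        if read == 0:
            x = np.zeros(m)
        elif read == 1 and init is not None:
            x = np.asarray(init, dtype=float).copy()
        else:
            x = rng.integers(0, 2, m).astype(float)
        h = d + O @ x
        e = float(x @ Q.coeffs @ x)
        inc_e, inc_x = e, x.copy()
        tabu_until = np.full(m, -1)
        nonimp = 0
        it = 0
        while nonimp < config.tabu_max_sweeps and it < hard_cap:
            deltas = _flip_deltas(x, h)
            admissible = (tabu_until <= it) | (e + deltas < inc_e)
            if np.any(admissible):
                p = int(np.where(admissible, deltas, np.inf).argmin())
            else:
                p = int(tabu_until.argmin())  # release the oldest tabu move
            s = 1.0 - 2.0 * x[p]
            x[p] = 1.0 - x[p]
            e += deltas[p]
            h += O[:, p] * s
            tabu_until[p] = it + tenure
            if e < inc_e:
                inc_e, inc_x = e, x.copy()
                nonimp = 0
            else:
                nonimp += 1
            it += 1
        evals += it * m
        if inc_e < best_e:
            best_e, best_x = inc_e, inc_x
    return _finish(Q, best_x, "tabu", evals)


def greedy_refine(Q: QuboProblem, x) -> SolutionRecord:
    """Steepest-descent single-bit flips until no flip improves the energy."""
    m = Q.m
    x = np.asarray(x, dtype=float).copy()
    if x.shape != (m,):
        raise ValidationError(f"bitstring length {x.shape} does not match m={m}")
    d = Q.linear()
    O = Q.symmetric_offdiag()
    h = d + O @ x
    evals = 0
    while True:
        deltas = _flip_deltas(x, h)
        p = int(deltas.argmin())
        evals += m
        if deltas[p] >= 0.0:
            break
        s = 1.0 - 2.0 * x[p]
        x[p] = 1.0 - x[p]
        h += O[:, p] * s
    return _finish(Q, x, "greedy", evals)


# ---------------------------------------------------------------------------
# subQUBO decomposition
# ---------------------------------------------------------------------------

def select_subqubo_variables(Q: QuboProblem, x, block_size: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Pick the variables of the next sub-problem (sorted indices).

    Half the block (rounded up) is the highest-impact variables — largest
    |single-flip energy delta| at the current x — and the remainder is a
    uniform random sample of the rest, for diversification.
    """
    m = Q.m
    if block_size > m:
        raise ValidationError(f"block_size {block_size} exceeds m={m}")
    if block_size == m:
        return np.arange(m)
    x = np.asarray(x, dtype=float)
    deltas = _flip_deltas(x, Q.linear() + Q.symmetric_offdiag() @ x)
    order = np.lexsort((np.arange(m), -np.abs(deltas)))  # impact rank, index ties
    n_top = -(-block_size // 2)  # ceil
    top = order[:n_top]
    pad = rng.choice(order[n_top:], size=block_size - n_top, replace=False)
    return np.sort(np.concatenate([top, pad]))


def clamp_subproblem(Q: QuboProblem, x, subset: np.ndarray) -> QuboProblem:
    """Sub-QUBO over ``subset`` with every other variable frozen at x.

    Frozen variables fold into the sub-problem's linear terms; their internal
    energy becomes the sub-problem ``constant``, so that for any sub-assignment
    y: qubo_energy(sub, y) + sub.constant == qubo_energy(Q, merge(x, y)).
    """
    x = np.asarray(x, dtype=float)
    subset = np.asarray(subset)
    fixed = np.setdiff1d(np.arange(Q.m), subset, assume_unique=False)
    sub_coeffs = Q.coeffs[np.ix_(subset, subset)].copy()  # stays upper-triangular
    O = Q.symmetric_offdiag()
    lin_shift = O[np.ix_(subset, fixed)] @ x[fixed]
    sub_coeffs[np.diag_indices_from(sub_coeffs)] += lin_shift
    x_fixed_only = x.copy()
    x_fixed_only[subset] = 0.0
    clamp_const = qubo_energy(Q, x_fixed_only)
    return QuboProblem(coeffs=sub_coeffs, constant=clamp_const,
                       lambda_used=Q.lambda_used)


def _run_inner(Q: QuboProblem, inner: InnerSolver, seed: int,
               init=None) -> SolutionRecord:
    """Dispatch to the inner solver; validate the sampler contract."""
    if callable(inner) and not isinstance(inner, SolverConfig):
        rec = inner(Q)
        x = np.asarray(getattr(rec, "x", None))
        if x is None or x.shape != (Q.m,):
            raise SamplerContractError(
                f"sampler returned bitstring of shape {getattr(x, 'shape', None)}, "
                f"expected ({Q.m},)"
            )
        if not np.isin(x, (0, 1)).all():
            raise SamplerContractError("sampler returned non-binary values")
        return _finish(Q, x, getattr(rec, "backend", "external"),
                       getattr(rec, "n_evaluations", 0))
    if inner.mode == "exact":
        return solve_exact(Q)
    if inner.mode == "tabu":
        return solve_tabu(Q, dataclasses.replace(inner, seed=seed), init=init)
    raise ValidationError(f"mode {inner.mode!r} cannot serve as an inner solver")


def solve_subqubo(Q: QuboProblem, sub: SubquboConfig, inner: InnerSolver,
                  seed: int = 0, init=None) -> SolutionRecord:
    """Block-decomposition minimizer for QUBOs too large for one solve.

    Start from a greedily refined random string; then ``sub.repeats`` times:
    select a block, clamp the rest, minimize the block with the inner solver,
    accept the merge iff the total energy does not increase, and greedily
    refine. Returns the best solution ever seen; the per-repeat best-so-far
    energies are recorded in ``trajectory``. Deterministic for a fixed seed.
    When m <= block_size the problem is handed to the inner solver once,
    seeded with ``seed``. ``init`` replaces the random start when given.
    """
    m = Q.m
    if m <= sub.block_size:
        return _run_inner(Q, inner, seed, init=init)
    if isinstance(inner, SolverConfig) and inner.mode == "exact" \
            and sub.block_size > EXACT_SOLVER_CAP:
        raise ValidationError(
            f"block_size {sub.block_size} exceeds the exact solver cap {EXACT_SOLVER_CAP}"
        )
    rng = np.random.default_rng(seed)
    start = rng.integers(0, 2, m).astype(float) if init is None \
        else np.asarray(init, dtype=float)
    rec = greedy_refine(Q, start)
    x, e = rec.x.astype(float), rec.energy
    evals = rec.n_evaluations
    best_e, best_x = e, x.copy()
    trajectory = []
    for rep in range(sub.repeats):
        subset = select_subqubo_variables(Q, x, sub.block_size, rng)
        subQ = clamp_subproblem(Q, x, subset)
        inner_seed = int(rng.integers(0, 2**31))
        try:
            srec = _run_inner(subQ, inner, inner_seed)
        except SamplerContractError:
            raise
        except SolverError as exc:
            raise SolverError(
                f"inner solver failed at repeat {rep} on block {subset.tolist()}: {exc}"
            ) from exc
        evals += srec.n_evaluations
        cand = x.copy()
        cand[subset] = srec.x
        cand_e = qubo_energy(Q, cand)
        if cand_e <= e:
            g = greedy_refine(Q, cand)
            x, e = g.x.astype(float), g.energy
            evals += g.n_evaluations
            if e < best_e:
                best_e, best_x = e, x.copy()
        trajectory.append(best_e)
        logger.debug("subqubo repeat %d: current %.12g best %.12g", rep, e, best_e)
    return _finish(Q, best_x, "subqubo", evals, trajectory=trajectory)


def minimize_qubo(Q: QuboProblem, config: SolverConfig,
                  sub: SubquboConfig | None = None,
                  sampler: Sampler | None = None,
                  init=None) -> SolutionRecord:
    """One entry point for all backends, as used by the eigensolver loop.

    In ``subqubo`` mode the inner solver is the injected ``sampler`` if given,
    otherwise Tabu with this config's settings. ``init`` is an optional warm
    start (used by the heuristic backends, ignored by exact enumeration).
    """
    if config.mode == "exact":
        return solve_exact(Q)
    if config.mode == "tabu":
        return solve_tabu(Q, config, init=init)
    sub = sub or SubquboConfig()
    inner: InnerSolver = sampler if sampler is not None \
        else dataclasses.replace(config, mode="tabu")
    return solve_subqubo(Q, sub, inner, seed=config.seed, init=init)
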