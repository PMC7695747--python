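"""The variational eigensolver workflow.

The smallest eigenvalue of a real symmetric matrix A is the minimum of the
Rayleigh-Ritz quotient R_A(v) = (v, Av)/(v, v). Encoding v on the fixed-point
bit grid turns the penalized objective

    F(v) = (v, Av) + lambda (v, v)

into a QUBO, minimized by one of the classical backends in
:mod:`qae.solvers`. The normalization penalty lambda is found automatically:
for large positive lambda the QUBO minimum is the null vector (trivial), for
large negative lambda it is not, and the useful lambda sits at the phase
transition between the two regimes. The workflow brackets that transition
(doubling an initial guess of +-max|A| as needed), shrinks the bracket by
bisection while recording every nontrivial solution's normalized expectation
value (v, Av), and finally reports the smallest recorded value with its
vector. Excited states follow by Brauer deflation, A' = A + mu (v0 x v0),
which shifts the found eigenvalue up by mu and leaves the rest of the
spectrum unchanged; n eigenpairs cost n serial ground-state runs.

Every run is deterministic for a fixed seed, and a JSON checkpoint written
after each completed state lets an interrupted multi-state calculation resume
with bit-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import EncodingSpec, build_qubo, decode_vector
from .errors import BracketingError, CheckpointError, SolverError, ValidationError
from .matrices import as_array
from .solvers import SolverConfig, SubquboConfig, Sampler, minimize_qubo

logger = logging.getLogger(__name__)

__all__ = [
    "Eigenpair",
    "LambdaBracket",
    "SpectrumConfig",
    "CheckpointState",
    "rayleigh_quotient",
    "classify_solution",
    "initial_bracket",
    "bisect_lambda",
    "solve_ground",
    "deflate",
    "solve_spectrum",
    "save_checkpoint",
    "load_checkpoint",
    "matrix_fingerprint",
]

CHECKPOINT_SCHEMA = 1

#: Cap on bracket-expansion doublings per end.
MAX_DOUBLINGS = 60


@dataclass
class Eigenpair:
    """An eigenvalue estimate: value = (v, Av) for the unit-norm vector v."""

    value: float
    vector: np.ndarray
    lambda_opt: float | None = None
    raw_vector: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {"value": self.value, "vector": [float(c) for c in self.vector]}
        if self.lambda_opt is not None:
            d["lambda_opt"] = self.lambda_opt
        if self.raw_vector is not None:
            d["raw_vector"] = [float(c) for c in self.raw_vector]
        return d


@dataclass
class LambdaBracket:
    """Penalty interval: nontrivial QUBO optimum at ``lo``, trivial at ``hi``."""

    lo: float
    hi: float

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class SpectrumConfig:
    """Workflow parameters.

    ``mu_multiplier`` scales the deflation shift (mu = multiplier x max|A|;
    16 by default, smaller powers of two behave essentially the same).
    ``tol_R`` stops the bisection when consecutive nontrivial expectation
    values agree to within it. It is 0 (disabled) by default: far from the
    phase transition the QUBO minimizer can mix several descent directions
    whose expectation value plateaus at a wrong level, and a tolerance
    criterion armed there stops the search prematurely. ``lambda_tol`` is
    the bracket-width floor and ``max_bisections`` a mandatory iteration cap —
    with noisy solvers the tolerance criterion alone may never trigger.
    ``trivial_eta`` is the null-vector norm threshold (default
    max(2*Delta, 1/8); see :func:`classify_solution`).
    """

    n_states: int = 1
    mu_multiplier: float = 16.0
    tol_R: float = 0.0
    lambda_tol: float = 1e-6
    max_bisections: int = 60
    trivial_eta: float | None = None

    def __post_init__(self):
        if self.n_states < 1:
            raise ValidationError("n_states must be >= 1")
        if self.mu_multiplier <= 0:
            raise ValidationError("mu_multiplier must be positive")
        if self.max_bisections < 1:
            raise ValidationError("max_bisections must be >= 1")


@dataclass
class _Record:
    """One nontrivial QUBO solution met during the lambda search."""

    lam: float
    raw_vector: np.ndarray
    vector: np.ndarray  # normalized
    value: float  # (v, Av) at unit norm


def rayleigh_quotient(A, v) -> float:
    """(v, Av) / (v, v); invariant under scaling of v."""
    a = as_array(A)
    v = np.asarray(v, dtype=float)
    nrm2 = float(v @ v)
    if nrm2 == 0.0:
        raise ValidationError("Rayleigh quotient undefined for the zero vector")
    return float(v @ a @ v) / nrm2


def classify_solution(v, spec: EncodingSpec, eta: float | None = None) -> str:
    """'trivial' if ||v|| <= eta (default max(2*Delta, 1/8)), else 'nontrivial'.

    A norm threshold, rather than an exact zero test, tolerates stray
    low-weight bits left by heuristic solvers. The 1/8 floor matters: just
    above the phase transition, minimizers often return near-null vectors a
    few grid steps long whose penalized objective marginally beats the exact
    null code. Their norm scales with Delta while a genuine solution's norm
    is O(1), so treating them as nontrivial would steer the bisection past
    the transition; the floor keeps them on the trivial side.
    """
    if eta is None:
        eta = max(2.0 * spec.delta, 0.125)
    return "trivial" if float(np.linalg.norm(v)) <= eta else "nontrivial"


def _solve_at_lambda(A, lam, spec, solver, sub, sampler, records, config,
                     warm=None):
    """Build and minimize the QUBO at one lambda; log and record nontrivial v.

    ``warm`` is a one-slot carrier {'x': bits or None} holding the last
    nontrivial solution: successive lambdas give nearly identical QUBOs, so
    the incumbent is handed to the heuristic backends as a warm start.
    """
    a = as_array(A)
    Q = build_qubo(a, lam, spec)
    init = warm.get("x") if warm is not None else None
    rec = minimize_qubo(Q, solver, sub=sub, sampler=sampler, init=init)
    v = decode_vector(rec.x, a.shape[0], spec)
    kind = classify_solution(v, spec, eta=config.trivial_eta)
    if kind == "nontrivial":
        if warm is not None:
            warm["x"] = rec.x
        vn = v / np.linalg.norm(v)
        value = float(vn @ a @ vn)
        records.append(_Record(lam=lam, raw_vector=v, vector=vn, value=value))
        best = min(r.value for r in records)
        logger.info("lambda=%.12g -> nontrivial, (v,Av)=%.12g, best=%.12g",
                    lam, value, best)
    else:
        logger.info("lambda=%.12g -> trivial", lam)
    return kind


def initial_bracket(A, spec: EncodingSpec, solver: SolverConfig,
                    config: SpectrumConfig | None = None,
                    sub: SubquboConfig | None = None,
                    sampler: Sampler | None = None,
                    records: list | None = None,
                    warm: dict | None = None) -> LambdaBracket:
    """Establish (lo nontrivial, hi trivial) around the phase transition.

    The largest matrix-element magnitude g seeds the ends as (-g, +g); an end
    of the wrong type is doubled, at most ``MAX_DOUBLINGS`` times.
    """
    config = config or SpectrumConfig()
    records = records if records is not None else []
    a = as_array(A)
    g = float(np.abs(a).max())
    if g == 0.0:
        raise ValidationError("cannot bracket lambda for the zero matrix")
    lo, hi = -g, g
    for _ in range(MAX_DOUBLINGS + 1):
        if _solve_at_lambda(a, lo, spec, solver, sub, sampler, records, config,
                            warm) == "nontrivial":
            break
        lo *= 2.0
    else:
        raise BracketingError(
            f"no nontrivial solution found down to lambda={lo:g}"
        )
    for _ in range(MAX_DOUBLINGS + 1):
        if _solve_at_lambda(a, hi, spec, solver, sub, sampler, records, config,
                            warm) == "trivial":
            break
        hi *= 2.0
    else:
        raise BracketingError(
            f"no trivial solution found up to lambda={hi:g}"
        )
    return LambdaBracket(lo=lo, hi=hi)


def bisect_lambda(A, bracket: LambdaBracket, spec: EncodingSpec,
                  solver: SolverConfig, config: SpectrumConfig,
                  sub: SubquboConfig | None = None,
                  sampler: Sampler | None = None,
                  records: list | None = None,
                  warm: dict | None = None):
    """Shrink the bracket by bisection, keeping end types invariant.

    Stops when consecutive recorded expectation values change by less than
    ``tol_R``, when the bracket is narrower than ``lambda_tol``, or after
    ``max_bisections`` midpoint solves. Returns (lambda_opt, records) with
    lambda_opt the final bracket midpoint.
    """
    records = records if records is not None else []
    a = as_array(A)
    prev_value = None
    for _ in range(config.max_bisections):
        if bracket.width < config.lambda_tol:
            break
        mid = bracket.midpoint
        kind = _solve_at_lambda(a, mid, spec, solver, sub, sampler, records,
                                config, warm)
        if kind == "nontrivial":
            bracket.lo = mid
            value = records[-1].value
            if prev_value is not None and abs(value - prev_value) < config.tol_R:
                break
            prev_value = value
        else:
            bracket.hi = mid
    return bracket.midpoint, records


def solve_ground(A, spec: EncodingSpec, solver: SolverConfig,
                 config: SpectrumConfig | None = None,
                 sub: SubquboConfig | None = None,
                 sampler: Sampler | None = None) -> Eigenpair:
    """Smallest eigenpair of A via the automated lambda search.

    All nontrivial solutions met during bracketing and bisection are stored;
    the one with the smallest normalized (v, Av) is returned.
    """
    config = config or SpectrumConfig()
    a = as_array(A)
    records: list[_Record] = []
    warm: dict = {"x": None}
    bracket = initial_bracket(a, spec, solver, config, sub, sampler, records,
                              warm)
    lambda_opt, records = bisect_lambda(a, bracket, spec, solver, config,
                                        sub, sampler, records, warm)
    if not records:
        raise SolverError("no nontrivial solution found during the lambda search")
    best = min(records, key=lambda r: r.value)
    return Eigenpair(value=best.value, vector=best.vector,
                     lambda_opt=lambda_opt, raw_vector=best.raw_vector)


def deflate(A, pair: Eigenpair, mu: float):
    """Brauer shift A + mu (v x v): moves the eigenvalue of the unit
    eigenvector v up by mu, leaving the remaining spectrum unchanged."""
    a = as_array(A)
    v = np.asarray(pair.vector, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValidationError("deflation requires a unit-norm eigenvector")
    if mu < 0:
        raise ValidationError("deflation shift mu must be non-negative")
    return a + mu * np.outer(v, v)


# ---------------------------------------------------------------------------
# Multi-state driver with checkpoint/restart
# ---------------------------------------------------------------------------

def matrix_fingerprint(A) -> str:
    a = np.ascontiguousarray(as_array(A))
    h = hashlib.sha256()
    h.update(str(a.shape).encode())
    h.update(a.tobytes())
    return h.hexdigest()


@dataclass
class CheckpointState:
    """Resumable snapshot of a multi-state run (state-boundary granularity)."""

    fingerprint: str
    pairs: list  # completed Eigenpairs (original-matrix values)
    mus: list  # deflation shift applied after each completed state
    next_state: int
    config_echo: dict = field(default_factory=dict)
    bracket: LambdaBracket | None = None  # populated mid-state only
    schema: int = CHECKPOINT_SCHEMA

    def to_json(self) -> str:
        return json.dumps({
            "schema": self.schema,
            "fingerprint": self.fingerprint,
            "next_state": self.next_state,
            "config": self.config_echo,
            "bracket": None if self.bracket is None
                       else {"lo": self.bracket.lo, "hi": self.bracket.hi},
            "pairs": [p.to_dict() for p in self.pairs],
            "mus": list(self.mus),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CheckpointState":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CheckpointError(f"unreadable checkpoint: {exc}") from exc
        if d.get("schema") != CHECKPOINT_SCHEMA:
            raise CheckpointError(f"unsupported checkpoint schema {d.get('schema')!r}")
        pairs = [
            Eigenpair(value=p["value"], vector=np.array(p["vector"]),
                      lambda_opt=p.get("lambda_opt"),
                      raw_vector=None if p.get("raw_vector") is None
                                 else np.array(p["raw_vector"]))
            for p in d["pairs"]
        ]
        br = d.get("bracket")
        return cls(fingerprint=d["fingerprint"], pairs=pairs, mus=d["mus"],
                   next_state=d["next_state"], config_echo=d.get("config", {}),
                   bracket=None if br is None else LambdaBracket(**br))


def save_checkpoint(state: CheckpointState, path) -> None:
    Path(path).write_text(state.to_json())


def load_checkpoint(path, A=None) -> CheckpointState:
    state = CheckpointState.from_json(Path(path).read_text())
    if A is not None and state.fingerprint != matrix_fingerprint(A):
        raise CheckpointError(
            "checkpoint fingerprint does not match the supplied matrix; "
            "refusing to resume"
        )
    return state


def solve_spectrum(A, spec: EncodingSpec, solver: SolverConfig,
                   config: SpectrumConfig,
                   sub: SubquboConfig | None = None,
                   sampler: Sampler | None = None,
                   checkpoint_path=None,
                   stop_after: int | None = None) -> list[Eigenpair]:
    """The lowest ``config.n_states`` eigenpairs by serial deflation.

    Each state runs :func:`solve_ground` on the current (deflated) matrix;
    its value and vector are then re-evaluated against the ORIGINAL A, and
    the matrix is deflated for the next state. All states use the same shift
    mu = mu_multiplier x max|A| of the original matrix: recomputing it from
    the deflated matrix would compound the shifts geometrically and bury the
    remaining spectral differences under the penalty scale. With ``checkpoint_path`` set, a checkpoint is written
    after every completed state and an existing compatible checkpoint is
    resumed from; ``stop_after`` ends the run early after that many states
    (the staged-run use case the checkpoint exists for).
    """
    a = as_array(A)
    if config.n_states > a.shape[0]:
        raise ValidationError(
            f"n_states={config.n_states} exceeds matrix dimension {a.shape[0]}"
        )
    fp = matrix_fingerprint(a)
    pairs: list[Eigenpair] = []
    mus: list[float] = []
    current = a.copy()
    start = 0
    if checkpoint_path is not None and Path(checkpoint_path).exists():
        state = load_checkpoint(checkpoint_path, a)
        pairs, mus, start = state.pairs, list(state.mus), state.next_state
        for p, mu in zip(pairs, mus):  # replay deflations bit-for-bit
            current = current + mu * np.outer(p.vector, p.vector)
        logger.info("resumed from checkpoint: %d state(s) done", start)
    config_echo = {
        "n_states": config.n_states, "mu_multiplier": config.mu_multiplier,
        "tol_R": config.tol_R, "lambda_tol": config.lambda_tol,
        "max_bisections": config.max_bisections, "K": spec.K,
        "mode": solver.mode, "seed": solver.seed,
    }
    for k in range(start, config.n_states):
        logger.info("=== state %d ===", k)
        try:
            ground = solve_ground(current, spec, solver, config, sub, sampler)
        except (SolverError, ValidationError) as exc:
            raise SolverError(f"state {k}: {exc}") from exc
        v = ground.vector
        pair = Eigenpair(value=float(v @ a @ v), vector=v,
                         lambda_opt=ground.lambda_opt,
                         raw_vector=ground.raw_vector)
        mu = config.mu_multiplier * float(np.abs(a).max())
        pairs.append(pair)
        mus.append(mu)
        current = current + mu * np.outer(v, v)
        logger.info("state %d: value=%.12g, lambda_opt=%.12g, mu=%.6g",
                    k, pair.value, pair.lambda_opt, mu)
        if checkpoint_path is not None:
            save_checkpoint(CheckpointState(fingerprint=fp, pairs=pairs,
                                            mus=mus, next_state=k + 1,
                                            config_echo=config_echo),
                            checkpoint_path)
        if stop_after is not None and len(pairs) >= stop_after:
            break
    return pairs
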