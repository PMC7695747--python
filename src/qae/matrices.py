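"""Symmetric-matrix I/O, synthetic test matrices and the dense reference oracle.

The eigensolver in this package operates on real symmetric matrices. In the
electronic-structure setting these are configuration-interaction Hamiltonians
(Hartree units) produced by external quantum-chemistry codes; this module does
not build such Hamiltonians. It reads/writes them (Matrix Market or plain
dense text), manufactures synthetic matrices with a prescribed spectrum for
validation, and wraps the dense symmetric eigensolver used as the reference.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.linalg
import scipy.sparse

from .errors import MatrixFormatError, ValidationError

#: Conversion factor between Hartree and kcal/mol (CODATA-derived).
HARTREE_TO_KCAL_PER_MOL = 627.509474

#: Relative asymmetry tolerated in "general" inputs before rejection.
ASYMMETRY_RTOL = 1e-12

__all__ = [
    "HARTREE_TO_KCAL_PER_MOL",
    "RealSymmetricMatrix",
    "SpectrumSpec",
    "ResultReport",
    "read_matrix",
    "write_matrix",
    "generate_matrix_with_spectrum",
    "reference_diagonalize",
    "energy_error_kcal",
    "as_array",
]


@dataclass(frozen=True)
class RealSymmetricMatrix:
    """An n-by-n real symmetric matrix (the operator to be diagonalized)."""

    entries: np.ndarray

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @classmethod
    def from_array(cls, arr, rtol: float = ASYMMETRY_RTOL) -> "RealSymmetricMatrix":
        """Validate, symmetrize as (M + M^T)/2 and wrap a square array.

        Inputs asymmetric beyond ``rtol`` (relative to the largest magnitude
        entry) are rejected, naming the worst offending index pair.
        """
        m = np.array(arr, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"expected a square matrix, got shape {m.shape}")
        if m.shape[0] == 0:
            raise ValidationError("empty matrix (n=0) is not a valid operator")
        if not np.all(np.isfinite(m)):
            raise ValidationError("matrix contains non-finite entries")
        scale = float(np.max(np.abs(m))) or 1.0
        asym = np.abs(m - m.T)
        worst = float(asym.max())
        if worst > rtol * scale:
            a, b = np.unravel_index(int(asym.argmax()), asym.shape)
            raise ValidationError(
                f"matrix is not symmetric: |M[{a},{b}] - M[{b},{a}]| = {worst:g} "
                f"exceeds {rtol:g} relative tolerance"
            )
        return cls(entries=(m + m.T) / 2.0)


def as_array(A) -> np.ndarray:
    """Return the underlying ndarray of a matrix-like argument."""
    return A.entries if isinstance(A, RealSymmetricMatrix) else np.asarray(A, dtype=float)


@dataclass(frozen=True)
class SpectrumSpec:
    """Requested eigenvalues (ascending) and the seed for the random basis."""

    eigenvalues: Sequence[float]
    seed: int

    def __post_init__(self):
        ev = np.asarray(self.eigenvalues, dtype=float)
        if ev.size < 1:
            raise ValidationError("spectrum must contain at least one eigenvalue")
        if not np.all(np.isfinite(ev)):
            raise ValidationError("spectrum contains non-finite values")
        if np.any(np.diff(ev) < 0):
            raise ValidationError("spectrum eigenvalues must be sorted ascending")


@dataclass(frozen=True)
class ResultReport:
    """Computed-vs-reference energy comparison, with the chemistry unit view."""

    E_computed: float
    E_ref: float

    @property
    def error_kcal(self) -> float:
        return energy_error_kcal(self.E_computed, self.E_ref)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_DENSE_COMMENT_CHARS = ("%", "#")


def _read_dense_text(path) -> np.ndarray:
    try:
        m = np.loadtxt(path, comments=list(_DENSE_COMMENT_CHARS), ndmin=2)
    except ValueError as exc:
        raise MatrixFormatError(f"cannot parse dense text matrix {path}: {exc}") from exc
    if m.size == 0:
        raise MatrixFormatError(f"no matrix data found in {path}")
    return m


def _read_matrix_market(path) -> np.ndarray:
    try:
        rows, cols, _entries, fmt, field, symmetry = scipy.io.mminfo(path)
    except ValueError as exc:
        raise MatrixFormatError(f"malformed Matrix Market header in {path}: {exc}") from exc
    if field not in ("real", "integer"):
        raise MatrixFormatError(f"unsupported Matrix Market field {field!r} (need real)")
    if symmetry not in ("general", "symmetric"):
        raise MatrixFormatError(
            f"unsupported Matrix Market symmetry {symmetry!r} (need general or symmetric)"
        )
    if rows != cols:
        raise ValidationError(f"matrix in {path} is {rows}x{cols}, not square")
    m = scipy.io.mmread(path)
    if scipy.sparse.issparse(m):
        m = m.toarray()
    return np.asarray(m, dtype=float)


def read_matrix(path, format: str = "auto") -> RealSymmetricMatrix:
    """Read a real symmetric matrix from ``path``.

    ``format`` is ``matrix-market``, ``dense-text`` or ``auto`` (decide by the
    ``.mtx`` extension / ``%%MatrixMarket`` banner). A Matrix Market file with
    ``general`` symmetry is accepted only if it is numerically symmetric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    if format == "auto":
        if path.suffix.lower() == ".mtx":
            format = "matrix-market"
        else:
            with open(path, "r") as fh:
                first = fh.readline()
            format = "matrix-market" if first.startswith("%%MatrixMarket") else "dense-text"
    if format == "matrix-market":
        raw = _read_matrix_market(path)
    elif format == "dense-text":
        raw = _read_dense_text(path)
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return RealSymmetricMatrix.from_array(raw)


def write_matrix(A, path, format: str = "auto") -> None:
    """Write a matrix so that :func:`read_matrix` reproduces it bit-identically.

    Matrix Market output uses symmetric storage (lower triangle only); both
    formats print 18 significant digits, enough for exact float64 round-trip.
    """
    arr = as_array(A)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] == 0:
        raise ValidationError(f"cannot write matrix of shape {arr.shape}")
    path = Path(path)
    if format == "auto":
        format = "matrix-market" if path.suffix.lower() == ".mtx" else "dense-text"
    if format == "matrix-market":
        # sparse lower triangle + symmetry flag -> coordinate symmetric storage
        lower = scipy.sparse.coo_matrix(np.tril(arr))
        buf = io.BytesIO()
        scipy.io.mmwrite(buf, lower, precision=17, symmetry="symmetric")
        path.write_bytes(buf.getvalue())
    elif format == "dense-text":
        np.savetxt(path, arr, fmt="%.17e")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


# ---------------------------------------------------------------------------
# Synthetic matrices and the dense reference
# ---------------------------------------------------------------------------

def random_orthogonal(n: int, seed: int) -> np.ndarray:
    """Seeded random orthogonal matrix: QR of a standard-normal draw with the
    R-diagonal sign fixed, which makes the result unique and reproducible."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def generate_matrix_with_spectrum(spec: SpectrumSpec) -> RealSymmetricMatrix:
    """Build Q^T diag(eigenvalues) Q for a seeded random orthogonal Q.

    The result is exactly symmetric and has the requested spectrum to
    numerical precision, which makes it the standard test fixture here:
    ground truth is known by construction.
    """
    ev = np.asarray(spec.eigenvalues, dtype=float)
    n = ev.size
    q = random_orthogonal(n, spec.seed)
    a = q.T @ (ev[:, None] * q)
    return RealSymmetricMatrix(entries=(a + a.T) / 2.0)


def reference_diagonalize(A):
    """Full dense diagonalization (ascending eigenvalues, orthonormal vectors).

    This is the classical oracle the iterative QUBO-based solver is validated
    against; any dense symmetric eigensolver satisfies the contract.
    """
    from .eigensolver import Eigenpair  # local import avoids a module cycle

    arr = as_array(A)
    vals, vecs = scipy.linalg.eigh(arr)
    return [
        Eigenpair(value=float(vals[k]), vector=np.array(vecs[:, k]))
        for k in range(arr.shape[0])
    ]


def energy_error_kcal(E1: float, E2: float) -> float:
    """Difference of two Hartree energies expressed in kcal/mol."""
    if not (np.isfinite(E1) and np.isfinite(E2)):
        raise ValidationError("energies must be finite")
    return (E1 - E2) * HARTREE_TO_KCAL_PER_MOL
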