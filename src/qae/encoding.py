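"""Fixed-point binary encoding of eigenvector elements and the QUBO build.

The eigensolver minimizes F(v) = (v, Av) + lambda (v, v) over vectors whose
elements live on a power-of-two grid. Each element is represented by K bits
q_1..q_K with weights w_i = 2^(i-K) and a fixed offset of -1:

    v_alpha = -1 + sum_i 2^(i-K) q_i^alpha

so the representable values are {-1 + k*Delta : k = 0..2^K - 1} with step
Delta = 2^(1-K). The highest-weight bit (w_K = 1) acts as the sign bit:
v_alpha < 0 exactly when it is 0. Because the map is affine in the bits,
F stays quadratic and expands directly into QUBO coefficients.

Bit layout: bits of element alpha occupy global indices [alpha*K, (alpha+1)*K),
lowest weight first. The qbsolv-style ``.qubo`` text round-trip below depends
on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MatrixFormatError, ValidationError
from .matrices import as_array

__all__ = [
    "EncodingSpec",
    "QuboProblem",
    "decode_element",
    "encode_element",
    "decode_vector",
    "encode_vector",
    "build_qubo",
    "qubo_energy",
    "write_qubo_file",
    "read_qubo_file",
]


@dataclass(frozen=True)
class EncodingSpec:
    """K-bits-per-element fixed-point encoding of the interval [-1, 1 - Delta]."""

    K: int = 10

    def __post_init__(self):
        if self.K < 1:
            raise ValidationError(f"K must be a positive integer, got {self.K}")

    @property
    def delta(self) -> float:
        """Quantization step 2^(1-K)."""
        return 2.0 ** (1 - self.K)

    @property
    def weights(self) -> np.ndarray:
        """Bit weights w_i = 2^(i-K), i = 1..K (lowest weight first)."""
        return 2.0 ** (np.arange(1, self.K + 1) - self.K)

    @property
    def vmin(self) -> float:
        return -1.0

    @property
    def vmax(self) -> float:
        return 1.0 - self.delta


def decode_element(bits, spec: EncodingSpec) -> float:
    """Decode K bits into the represented real value: -1 + sum w_i b_i."""
    b = np.asarray(bits)
    if b.shape != (spec.K,):
        raise ValidationError(f"expected {spec.K} bits, got shape {b.shape}")
    return float(-1.0 + spec.weights @ b)


def _codes_to_bits(codes: np.ndarray, K: int) -> np.ndarray:
    """Integer grid codes k -> bit rows (lowest weight first)."""
    return (codes[:, None] >> np.arange(K)) & 1


def encode_array(values, spec: EncodingSpec) -> np.ndarray:
    """Vectorized nearest-grid-point encoder; returns (len, K) bit array.

    Values outside [-1, 1 - Delta] clamp to the nearest end; exact half-step
    ties round toward the representable value nearer zero.
    """
    t = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("cannot encode non-finite values")
    t = np.clip(t, spec.vmin, spec.vmax)
    scaled = (t - spec.vmin) / spec.delta  # exact: division by a power of two
    lo = np.floor(scaled)
    frac = scaled - lo
    k = np.where(frac > 0.5, lo + 1, lo)
    # break exact ties toward zero: pick whichever neighbour has smaller |v|
    ties = frac == 0.5
    if np.any(ties):
        v_lo = spec.vmin + lo * spec.delta
        toward_zero = np.where(np.abs(v_lo) <= np.abs(v_lo + spec.delta), lo, lo + 1)
        k = np.where(ties, toward_zero, k)
    return _codes_to_bits(k.astype(np.int64), spec.K)


def encode_element(value: float, spec: EncodingSpec) -> np.ndarray:
    """Bits of the representable value nearest to ``value`` (see encode_array)."""
    return encode_array([value], spec)[0]


def decode_vector(x, n: int, spec: EncodingSpec) -> np.ndarray:
    """Decode an n*K bitstring into the n-element real vector it represents."""
    b = np.asarray(x)
    if b.shape != (n * spec.K,):
        raise ValidationError(
            f"bitstring length {b.shape} does not match n*K = {n}*{spec.K}"
        )
    return -1.0 + b.reshape(n, spec.K) @ spec.weights


def encode_vector(v, spec: EncodingSpec) -> np.ndarray:
    """Elementwise encode; returns the flat n*K bitstring."""
    return encode_array(v, spec).reshape(-1)


@dataclass
class QuboProblem:
    """Upper-triangular QUBO coefficients plus the tracked additive constant.

    ``coeffs`` is a dense (m, m) array with the strictly-lower triangle zero;
    entry (i, i) is the linear term of variable i and entry (i, j), i < j, the
    (already doubled) coupler. ``constant`` is the term dropped from the
    binary polynomial, so that for any bitstring x

        qubo_energy(Q, x) + Q.constant == (v, Av) + lambda (v, v),  v = decode(x).
    """

    coeffs: np.ndarray
    constant: float = 0.0
    lambda_used: float | None = None

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[0] != self.coeffs.shape[1]:
            raise ValidationError(f"QUBO coefficient array must be square, got {self.coeffs.shape}")
        if np.any(np.tril(self.coeffs, -1) != 0.0):
            raise ValidationError("QUBO coefficients must be upper-triangular (i <= j)")

    @property
    def m(self) -> int:
        return self.coeffs.shape[0]

    def symmetric_offdiag(self) -> np.ndarray:
        """Coupler matrix mirrored to full symmetric form, zero diagonal."""
        upper = np.triu(self.coeffs, 1)
        return upper + upper.T

    def linear(self) -> np.ndarray:
        return np.diag(self.coeffs).copy()


def build_qubo(A, lam: float, spec: EncodingSpec) -> QuboProblem:
    """Expand F(v) = (v, Av) + lambda (v, v) over the bit variables.

    With B = A + lambda I and v_alpha = u_alpha - 1, u_alpha = sum_i w_i q_i,

        F = sum_ab B_ab u_a u_b  -  2 sum_a (sum_b B_ab) u_a  +  sum_ab B_ab.

    Quadratic bit products with i < j are doubled into the upper triangle,
    same-bit squares use q^2 = q and fold into the diagonal together with the
    linear offset term; the trailing constant is tracked in ``constant``.
    """
    a = as_array(A)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"matrix must be square, got {a.shape}")
    if not np.allclose(a, a.T, rtol=0, atol=1e-12 * max(1.0, np.abs(a).max())):
        raise ValidationError("build_qubo requires a symmetric matrix")
    n = a.shape[0]
    b = a + lam * np.eye(n)
    w = spec.weights
    full = np.kron(b, np.outer(w, w))  # full[aK+i, bK+j] = B_ab w_i w_j
    lin = np.diag(full) - 2.0 * np.kron(b.sum(axis=1), w)
    coeffs = np.triu(2.0 * full, 1) + np.diag(lin)
    return QuboProblem(coeffs=coeffs, constant=float(b.sum()), lambda_used=float(lam))


def qubo_energy(Q: QuboProblem, x) -> float:
    """sum_{i<=j} Q_ij x_i x_j for a binary string x (constant excluded)."""
    b = np.asarray(x, dtype=float)
    if b.shape != (Q.m,):
        raise ValidationError(f"bitstring length {b.shape} does not match m={Q.m}")
    return float(b @ Q.coeffs @ b)


# ---------------------------------------------------------------------------
# qbsolv-style .qubo text files
# ---------------------------------------------------------------------------

def write_qubo_file(Q: QuboProblem, path) -> None:
    """Write the qbsolv text dialect.

    Layout: ``c`` comment lines (carrying the tracked constant and lambda so a
    round-trip restores them), one ``p qubo 0 maxNodes nNodes nCouplers``
    program line, node lines ``i i value`` and coupler lines ``i j value``
    with i < j. Coefficients print with 17 significant digits (bit-exact
    float64 round-trip).
    """
    diag = Q.linear()
    upper = np.triu(Q.coeffs, 1)
    nodes = np.nonzero(diag)[0]
    couplers = np.argwhere(upper != 0.0)
    lines = ["c generated by qae"]
    lines.append(f"c constant = {Q.constant:.17g}")
    if Q.lambda_used is not None:
        lines.append(f"c lambda = {Q.lambda_used:.17g}")
    lines.append(f"p qubo 0 {Q.m} {len(nodes)} {len(couplers)}")
    for i in nodes:
        lines.append(f"{i} {i} {diag[i]:.17g}")
    for i, j in couplers:
        lines.append(f"{i} {j} {upper[i, j]:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_qubo_file(path) -> QuboProblem:
    """Parse the qbsolv text dialect written by :func:`write_qubo_file`."""
    constant = 0.0
    lambda_used = None
    coeffs = None
    m = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("c"):
            parts = line.split()
            if len(parts) == 4 and parts[1] == "constant" and parts[2] == "=":
                constant = float(parts[3])
            elif len(parts) == 4 and parts[1] == "lambda" and parts[2] == "=":
                lambda_used = float(parts[3])
            continue
        if line.startswith("p"):
            parts = line.split()
            if len(parts) != 6 or parts[1] != "qubo":
                raise MatrixFormatError(f"{path}:{lineno}: malformed program line {line!r}")
            m = int(parts[3])
            if m < 1:
                raise MatrixFormatError(f"{path}:{lineno}: maxNodes must be positive")
            coeffs = np.zeros((m, m))
            continue
        if coeffs is None:
            raise MatrixFormatError(f"{path}:{lineno}: data line before program line")
        parts = line.split()
        if len(parts) != 3:
            raise MatrixFormatError(f"{path}:{lineno}: expected 'i j value', got {line!r}")
        i, j, val = int(parts[0]), int(parts[1]), float(parts[2])
        if not (0 <= i < m and 0 <= j < m):
            raise MatrixFormatError(f"{path}:{lineno}: index out of range for maxNodes={m}")
        if i > j:
            raise MatrixFormatError(f"{path}:{lineno}: coupler line with i > j ({i} {j})")
        coeffs[i, j] = val
    if coeffs is None:
        raise MatrixFormatError(f"{path}: missing program line")
    return QuboProblem(coeffs=coeffs, constant=constant, lambda_used=lambda_used)
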