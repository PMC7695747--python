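"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code (see :mod:`qae.cli`).
"""


class QaeError(Exception):
    """Base class for all package errors."""


class MatrixFormatError(QaeError):
    """Malformed matrix or .qubo file (bad header, bad line, wrong shape)."""


class ValidationError(QaeError):
    """Input violates a contract (asymmetry, non-finite entries, bad sizes)."""


class SolverError(QaeError):
    """A QUBO solver or the eigensolver workflow failed."""


class BracketingError(SolverError):
    """The automated lambda bracket could not be established."""


class SamplerContractError(SolverError):
    """An injected sampler returned a malformed solution."""


class CheckpointError(QaeError):
    """Checkpoint file unusable or does not match the supplied matrix."""
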