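"""Exception hierarchy shared across the pipeline.

``InvalidInputError`` subclasses ``ValueError`` so callers using plain
``except ValueError`` still catch malformed inputs; numerical failures
(``GenerationError``, ``DivergenceError``) are kept distinct so the CLI can
map them to a different exit code.
"""


class ConnageError(Exception):
    """Base class for package errors."""


class InvalidInputError(ConnageError, ValueError):
    """Malformed or inconsistent input (bad shapes, missing columns, ...)."""


class GenerationError(ConnageError, ArithmeticError):
    """Synthetic-data construction failed (e.g. covariance not repairable)."""


class DivergenceError(ConnageError, ArithmeticError):
    """Model training produced non-finite loss."""
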