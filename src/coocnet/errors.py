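"""Exception hierarchy.

``InputError`` covers malformed or infeasible inputs (CLI exit code 2),
``ConvergenceError`` covers iterative procedures that fail to settle
(CLI exit code 3).
"""


class CoocnetError(Exception):
    """Base class for all package errors."""


class InputError(CoocnetError, ValueError):
    """Invalid or infeasible input data or parameters."""


class EmptyTableError(InputError):
    """An abundance table lost all of its species."""


class ConvergenceError(CoocnetError, RuntimeError):
    """An iterative algorithm did not converge within its budget."""

    def __init__(self, message, iterate=None):
        super().__init__(message)
        self.iterate = iterate
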