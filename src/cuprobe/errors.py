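"""Exception hierarchy.

``ValueError`` (and the :class:`ConfigurationError` / :class:`CSVFormatError`
subclasses) signal bad user input; :class:`SolverError` and :class:`FitError`
signal numerical failure of an otherwise well-posed problem. The CLI maps the
former to exit code 2 and the latter to exit code 3.
"""


class CuprobeError(Exception):
    """Base class for package-specific failures."""


class ConfigurationError(CuprobeError, ValueError):
    """Inconsistent binding-model / composition configuration."""


class CSVFormatError(CuprobeError, ValueError):
    """Malformed titration CSV; carries row/column diagnostics in the message."""


class SolverError(CuprobeError):
    """Speciation root-find did not meet its residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class FitError(CuprobeError):
    """Nonlinear fit failed outright (distinct from a flagged, non-converged result)."""
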