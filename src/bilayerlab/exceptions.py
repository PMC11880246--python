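"""Exception hierarchy shared across the package."""


class BilayerlabError(Exception):
    """Base class for all package errors."""


class DomainError(BilayerlabError, ValueError):
    """An argument lies outside the mathematical domain of an equation."""


class UnsupportedEquationError(BilayerlabError, ValueError):
    """The requested closed-form equation does not cover this bath composition."""


class NoSolutionError(BilayerlabError, ValueError):
    """The inverse problem has no admissible solution for the given inputs."""


class AmbiguousRootError(BilayerlabError, ValueError):
    """Multiple roots were bracketed where a unique one was expected.

    Carries ``brackets``: the list of (lo_mV, hi_mV) intervals containing a
    sign change.
    """

    def __init__(self, message: str, brackets: list[tuple[float, float]]):
        super().__init__(message)
        self.brackets = brackets


class ReversalUndefinedError(BilayerlabError, ValueError):
    """A zero-slope I-V line has no x-intercept."""


class InputError(BilayerlabError, ValueError):
    """Malformed or empty input data."""


class DegenerateFitError(BilayerlabError, RuntimeError):
    """A two-component fit is not identifiable (e.g. unimodal histogram).

    Carries ``single_fit``: the best single-component fit, when available.
    """

    def __init__(self, message: str, single_fit=None):
        super().__init__(message)
        self.single_fit = single_fit


class FitError(BilayerlabError, RuntimeError):
    """Nonlinear fit failed to converge; the message carries diagnostics."""


# Deliberately not a ValueError: pydantic would swallow it inside validators.
class ConfigError(BilayerlabError):
    """Pipeline configuration failed validation; message lists all violations."""
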