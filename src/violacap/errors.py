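"""Exception hierarchy shared across the package."""


class ViolacapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ViolacapError):
    """A table or config file does not have the expected layout."""


class ValidationError(ViolacapError, ValueError):
    """A record violates a type invariant (e.g. negative count)."""


class EmptyInputError(ViolacapError, ValueError):
    """An operation requiring data received an empty collection."""


class DomainError(ViolacapError, ValueError):
    """A numeric argument is outside the operation's domain."""


class FitFailureError(ViolacapError):
    """Maximum-likelihood fitting did not converge."""


class DegenerateFitError(FitFailureError):
    """The data admit no finite MLE (e.g. all segment densities zero)."""


class UsageError(ViolacapError):
    """An operation was called with inconsistent or insufficient inputs."""
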