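"""Exception hierarchy shared across the package."""


class RacewayRSMError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(RacewayRSMError):
    """The requested experimental design is not constructible."""


class DimensionError(RacewayRSMError):
    """A vector does not match the number of factors."""


class SingularFitError(RacewayRSMError):
    """The model matrix is rank deficient; names the collinear terms."""


class PureErrorUnavailableError(RacewayRSMError):
    """No replicated design points, so pure error cannot be estimated."""


class DegenerateRangeError(RacewayRSMError):
    """A response range with zero or negative width."""


class UndefinedDiagnosticsError(RacewayRSMError):
    """Diagnostics are undefined (e.g. constant response, SStot = 0)."""


class UndefinedRemovalError(RacewayRSMError):
    """Removal percentage undefined for a zero inlet concentration."""


class SchemaError(RacewayRSMError):
    """An input table or season label does not match the expected schema."""


class FixtureChecksumError(RacewayRSMError):
    """The bundled design/response fixture failed its integrity check."""
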