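"""Exception hierarchy shared across the package."""


class DScoreKitError(Exception):
    """Base class for all package errors."""


class ParseError(DScoreKitError):
    """A data file could not be parsed; the message names the offending row."""


class ConfigurationError(DScoreKitError):
    """Invalid configuration, e.g. unknown age unit or empty quadrature grid."""


class FixtureLookupError(DScoreKitError, KeyError):
    """Requested packaged fixture does not exist."""


class InsufficientDataError(DScoreKitError):
    """Too few observations/items to carry out the requested computation."""


class DomainError(DScoreKitError, ValueError):
    """Numeric input outside the mathematical domain of the operation."""


class DegenerateTransformError(DScoreKitError):
    """Anchor items have identical logit difficulties; no affine map exists."""


class ConnectivityWarning(UserWarning):
    """The discordant item-pair graph is not connected."""


class ExtrapolationWarning(UserWarning):
    """Age outside the reference range; value clamped to the nearest knot."""
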