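"""Exception hierarchy shared across the analysis stages."""


class ThermotacticsError(ValueError):
    """Base class for all analysis errors raised by this package."""


class InvalidRequestError(ThermotacticsError):
    """A call was made with arguments outside the operation's domain."""


class DegenerateInputError(ThermotacticsError):
    """Input carries no usable variation (constant series, zero row, ...)."""


class EmptyResultError(ThermotacticsError):
    """A filtering or aggregation step produced an empty result."""


class UnderdeterminedDesignError(ThermotacticsError):
    """Too few observations for the number of predictors after deletion."""


class InvalidBandsError(ThermotacticsError):
    """Scale bands do not form a contiguous partition of the harmonics."""


class MissingProfileError(ThermotacticsError):
    """A thermal-profile column has too few observed depths."""


class UndefinedOccupancyError(ThermotacticsError):
    """Epilimnion occupancy is undefined for an unstratified hour."""


class AmbiguousOrderError(ThermotacticsError):
    """Telemetry fixes cannot be ordered (duplicate timestamps)."""
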