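"""Exception hierarchy for whittlemle."""


class WhittleMLEError(Exception):
    """Base class for all whittlemle errors."""


class LengthError(WhittleMLEError, ValueError):
    """Input series is too short for the requested operation."""


class ZeroVarianceError(WhittleMLEError, ValueError):
    """Input series is constant; standardization is undefined."""


class DomainError(WhittleMLEError, ValueError):
    """A parameter or frequency lies outside its admissible domain."""


class ConvergenceError(WhittleMLEError, RuntimeError):
    """The bounded minimizer exhausted its iteration budget."""


class NotPositiveDefiniteError(WhittleMLEError, ValueError):
    """The fGn covariance matrix failed its Cholesky factorization."""


class SizeError(WhittleMLEError, ValueError):
    """Requested problem size exceeds a hard cap."""


class NonStationaryError(WhittleMLEError, ValueError):
    """AR polynomial has roots on or inside the unit circle."""


class DegenerateError(WhittleMLEError, ValueError):
    """A fluctuation function value of zero makes the log-log fit undefined."""
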