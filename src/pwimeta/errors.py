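"""Exception hierarchy shared across the package."""


class PwimetaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PwimetaError):
    """A required column or structural feature of an input file is missing."""


class ParseError(PwimetaError):
    """A cell could not be parsed; carries the offending row number."""


class InsufficientDataError(PwimetaError):
    """Too few observations to compute the requested quantity."""


class DegenerateProfileError(PwimetaError):
    """A delta profile has a zero slope denominator; the unit is excluded."""


class ConvergenceError(PwimetaError):
    """MCMC diagnostics breached after the allowed number of retries."""

    def __init__(self, message: str, rhat_max: float, ess_min: float):
        super().__init__(message)
        self.rhat_max = rhat_max
        self.ess_min = ess_min


class PrecisionError(PwimetaError):
    """Too few posterior draws for a stable density estimate."""
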