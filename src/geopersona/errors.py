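"""Exception types shared across the package."""


class GeopersonaError(Exception):
    """Base class for package errors."""


class ConfigurationError(GeopersonaError):
    """Invalid simulation or scoring configuration (bad sigma, empty lexicon...)."""


class DataError(GeopersonaError):
    """Malformed input data (upper < lower, bad polygon ring, misaligned rows)."""


class DegenerateError(GeopersonaError):
    """A computation is undefined on this input (constant column, zero variance)."""


class InsufficientDataError(GeopersonaError):
    """Too few observations for the requested statistic."""


class ScreeningFailureError(GeopersonaError):
    """No instrument candidate survived screening for some trait."""


class DesignError(GeopersonaError):
    """Rank-deficient or otherwise unidentifiable regression design."""
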