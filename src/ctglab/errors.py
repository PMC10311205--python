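"""Exception hierarchy shared across the package."""


class CTGError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CTGError):
    """Malformed input file (bad header, missing channel, schema mismatch)."""


class SamplingError(CTGError):
    """Time axis is not uniformly sampled."""


class EmptyInputError(CTGError):
    """Input contains no data."""


class LengthError(CTGError):
    """A series is too short for the requested operation."""


class AlignmentError(CTGError):
    """Series that must share one time axis do not."""


class DegenerateFitError(CTGError):
    """A model fit was requested on single-class or otherwise degenerate data."""


class UndefinedMetricError(CTGError):
    """A metric (e.g. AUC) is undefined for the given labels."""


class ParamsError(CTGError):
    """Simulation parameters are invalid or infeasible."""


class ConfigError(CTGError):
    """Unknown or malformed configuration keys."""
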