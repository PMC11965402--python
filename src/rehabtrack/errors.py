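"""Exception types shared across the package."""


class RehabtrackError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RehabtrackError, ValueError):
    """A landmark file does not conform to the expected dialect."""


class DegenerateGeometryError(RehabtrackError, ValueError):
    """A geometric quantity is undefined (zero-length vector, coincident
    landmarks, zero torso size).  Raised instead of silently emitting NaN."""


class UndefinedStatisticError(RehabtrackError, ValueError):
    """A statistic is undefined for the given input (e.g. zero total
    variance for R-squared, a single group for the ICC)."""
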