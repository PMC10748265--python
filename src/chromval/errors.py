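"""Exception hierarchy for chromatographic validation errors."""


class ChromValError(ValueError):
    """Base class for all chromval-specific errors."""


class DegenerateDesignError(ChromValError):
    """Calibration design cannot support a fit (too few distinct levels, etc.)."""


class PeakWindowError(ChromValError):
    """A peak or integration window falls outside the chromatographic run."""


class AmbiguousAssignmentError(ChromValError):
    """A detected peak matches more than one expected analyte within tolerance."""


class UndefinedTailingError(ChromValError):
    """The 5%-height level needed for the tailing factor is not bracketed."""
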