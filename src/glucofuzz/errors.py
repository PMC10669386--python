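"""Exception hierarchy shared across the package."""


class GlucofuzzError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GlucofuzzError, ValueError):
    """A numeric input violates its domain contract (non-finite, out of range)."""


class DegenerateFitError(GlucofuzzError, ValueError):
    """Calibration cannot be fit: undersized or rank-deficient design."""


class NoRuleFiredError(GlucofuzzError, ValueError):
    """Defuzzification requested on an all-zero aggregated curve."""


class ConfigurationError(GlucofuzzError, ValueError):
    """A fuzzy-system or cohort specification violates its invariants."""


class FixtureLookupError(GlucofuzzError, KeyError):
    """Unknown packaged fixture name."""


class InputFormatError(GlucofuzzError, ValueError):
    """A measurement table does not conform to the expected schema."""
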