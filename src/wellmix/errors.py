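"""Exception hierarchy for wellmix."""


class WellmixError(Exception):
    """Base class for all wellmix errors."""


class InvalidGeometryError(WellmixError, ValueError):
    """Well dimensions or grid sizes violate their constraints."""


class InvalidConfigError(WellmixError, ValueError):
    """A pipette or run configuration violates its constraints."""


class InvalidParameterError(WellmixError, ValueError):
    """A numerical parameter is outside its admissible range."""


class CalibrationError(WellmixError, RuntimeError):
    """No constant pair in the search grid reproduces all anchors."""


class IncompleteSweepError(WellmixError, KeyError):
    """A requested parameter combination is missing from a sweep table."""


class SurveyFormatError(WellmixError, ValueError):
    """The survey fixture is malformed."""


class StrokeCountParseError(SurveyFormatError):
    """A raw stroke-count expression could not be normalized."""


class EmptyDatasetError(WellmixError, ValueError):
    """An operation that needs at least one record received none."""


class UndefinedNormalizationError(WellmixError, ZeroDivisionError):
    """The reference concentration field is uniform, so the normalized
    variance is undefined."""
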