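"""Exception hierarchy for capscore.

All package-raised errors derive from :class:`CapscoreError` so callers can
catch the whole family with one clause; the subclasses distinguish bad user
input, malformed annotations, failed measurements, configuration problems
and tabular schema violations.
"""


class CapscoreError(Exception):
    """Base class for all capscore errors."""


class InvalidInputError(CapscoreError, ValueError):
    """A scalar input violates a precondition (negative count, NaN thickness, ...)."""


class AnnotationError(CapscoreError):
    """A polygonal annotation is structurally inconsistent (non-nested layers,
    swapped contours, capillary without a lumen)."""


class MeasurementError(CapscoreError):
    """A geometric measurement could not be completed on an otherwise valid
    annotation (e.g. no ray intersects the basement membrane)."""


class ConfigError(CapscoreError):
    """A configuration value is out of range or internally inconsistent."""


class SchemaError(CapscoreError):
    """A delimited input table is missing mandatory columns or has an
    unreadable header."""
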