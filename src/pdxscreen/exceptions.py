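"""Exception hierarchy shared across the package.

All errors raised by pdxscreen derive from :class:`PdxScreenError` so callers
can catch domain failures without masking programming errors.
"""


class PdxScreenError(Exception):
    """Base class for all pdxscreen errors."""


class InvalidMeasurementError(PdxScreenError):
    """A caliper measurement violates its physical constraints."""


class InvalidInputError(PdxScreenError):
    """A scalar input is outside its documented domain."""


class NotEvaluableError(PdxScreenError):
    """A growth series cannot support the requested response call."""


class EmptyCohortError(PdxScreenError):
    """A cohort summary was requested with zero evaluable calls."""


class InsufficientDataError(PdxScreenError):
    """Too few observations for the requested estimate."""


class UnclassifiableError(PdxScreenError):
    """A biomarker panel carries no usable rule inputs."""


class DegenerateLabelsError(PdxScreenError):
    """A two-class procedure received labels from a single class."""


class NormalizationError(PdxScreenError):
    """A relative readout is missing its vehicle/reference condition."""


class DegenerateOutcomeError(PdxScreenError):
    """A regression outcome has no variation."""


class ConfigError(PdxScreenError):
    """A synthetic-data configuration is invalid."""


class SchemaError(PdxScreenError):
    """A tabular input failed schema validation."""
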