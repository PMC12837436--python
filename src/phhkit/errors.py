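"""Exception hierarchy.

Every error raised by phhkit derives from :class:`PhhkitError`, split into
input/schema problems (bad files, bad configuration) and computation problems
(degenerate inputs discovered mid-analysis).  The CLI maps the two families to
distinct exit codes.
"""


class PhhkitError(Exception):
    """Base class for all phhkit errors."""


class SchemaError(PhhkitError):
    """Input file or table does not match the documented schema/format."""


class FormatError(SchemaError):
    """Image file has an unsupported layout, bit depth or channel count."""


class DimensionError(SchemaError):
    """Array shapes that must agree do not."""


class ConfigurationError(SchemaError):
    """Invalid configuration value (spacing, grid, fractions, paths...)."""


class ComputationError(PhhkitError):
    """A well-formed input turned out to be degenerate for the analysis."""


class UndefinedRatioError(ComputationError):
    """No blue or pink pixels: the stain ratio has an empty denominator."""


class CalibrationError(ComputationError):
    """Threshold calibration is impossible (e.g. a class has no patches)."""


class LabelingError(ComputationError):
    """A segmentation mask contains a label outside the compartment enum."""


class ConsistencyError(ComputationError):
    """Records that must agree (e.g. slice thickness within a scan) do not."""


class EmptyInputError(ComputationError):
    """An operation received an empty collection."""


class MappingError(ComputationError):
    """A subject has no group assignment (or an ambiguous one)."""


class DegeneratePredictorError(ComputationError):
    """Regression predictor has no variance (all days identical)."""
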