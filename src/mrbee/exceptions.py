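"""Exception hierarchy for mrbee.

All package-specific failures derive from :class:`MrbeeError` so callers can
catch one base class at the CLI boundary.
"""


class MrbeeError(Exception):
    """Base class for all mrbee errors."""


class ColumnMappingError(MrbeeError, KeyError):
    """A mandatory column role is missing from the column map or the file."""


class EmptyInputError(MrbeeError, ValueError):
    """An input table contained no usable rows."""


class EmptyIntersectionError(MrbeeError, ValueError):
    """No variant is shared across all studies being harmonized."""


class EmptySelectionError(MrbeeError, ValueError):
    """Instrument selection left no variants."""


class StandardizationStateError(MrbeeError, ValueError):
    """A panel is already standardized, or lacks what a mode requires."""


class InsufficientDataError(MrbeeError, ValueError):
    """Too few observations to estimate the requested quantity."""


class ShapeError(MrbeeError, ValueError):
    """Dimension mismatch between panels, covariance blocks, or hypotheses."""


class SingularCorrectionError(MrbeeError, ValueError):
    """The bias-corrected Jacobian is (near-)singular: the measurement-error
    correction exceeds the instrument signal. Use fewer or stronger IVs."""


class OverPruningError(MrbeeError, ValueError):
    """Outlier removal would leave too few instruments to fit the model."""


class AlignmentError(MrbeeError, ValueError):
    """Multi-outcome inputs do not share the same instrument set."""


class HypothesisDegeneracyError(MrbeeError, ValueError):
    """The hypothesis contrast has a singular covariance."""


class ClassificationError(MrbeeError, ValueError):
    """A locus lacks the evidence needed for pathway classification."""


class DomainError(MrbeeError, ValueError):
    """A numeric argument is outside its admissible domain."""


class ConfigurationError(MrbeeError, ValueError):
    """An invalid option, tag, or configuration value was supplied."""
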