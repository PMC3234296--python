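"""Exception hierarchy.

Everything raised on purpose by ampeff derives from :class:`AmpeffError`,
so callers (and the CLI) can catch one type.
"""


class AmpeffError(Exception):
    """Base class for all ampeff errors."""


class InvalidSequenceError(AmpeffError, ValueError):
    """A DNA sequence is empty, too short, or contains non-ACGT characters."""


class ConfigurationError(AmpeffError, ValueError):
    """An option value is unknown or inconsistent (e.g. odd palindrome length)."""


class NoAmplificationError(AmpeffError):
    """A fluorescence curve shows no visible amplification (maps to E = 1)."""


class FitError(AmpeffError):
    """A nonlinear fit failed to converge or produced invalid parameters."""


class EstimationError(AmpeffError):
    """Efficiency cannot be read off a fitted curve (exponential phase unseen)."""


class SchemaError(AmpeffError, ValueError):
    """A table is missing required columns."""


class DegenerateDesignError(AmpeffError, ValueError):
    """A model covariate is constant or otherwise rank-deficient."""


class ConstantInputError(AmpeffError, ValueError):
    """A statistic is undefined because an input vector is constant."""


class UndefinedCurveError(AmpeffError, ValueError):
    """ROC/PR curves are undefined because only one class is present."""


class ModelIOError(AmpeffError):
    """A model file cannot be parsed."""


class UnsupportedVersionError(ModelIOError):
    """A model file was written by an incompatible format version."""


class IncomparableModelsError(AmpeffError, ValueError):
    """AIC comparison requested between models fitted on different data."""


class FeatureUnavailableError(AmpeffError):
    """An optional capability (external primer-design executable) is absent."""
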