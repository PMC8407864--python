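"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`EwasMetaError` so callers (and the
CLI) can distinguish configuration mistakes from data problems.
"""


class EwasMetaError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(EwasMetaError):
    """A configuration value is out of range or internally inconsistent."""


class UnknownProbeError(EwasMetaError):
    """A probe id was referenced that does not exist in the dataset/annotation."""


class DegenerateExposureError(EwasMetaError):
    """Exposure has zero variance (or too few values) and cannot be standardized."""


class UnidentifiableReferenceError(EwasMetaError):
    """Cell-type reference is rank deficient on the probes shared with the data."""


class RankDeficiencyError(EwasMetaError):
    """Regression design matrix is rank deficient; names the collinear columns."""


class StratumTooSmallError(EwasMetaError):
    """A sex stratum has fewer samples than the configured minimum."""


class InsufficientDataError(EwasMetaError):
    """Too few observations for the requested statistic."""


class DegenerateModeratorError(EwasMetaError):
    """Meta-regression moderator is constant across cohorts."""


class EmptyAnalysisError(EwasMetaError):
    """No cohorts (or probes) remain after subsetting."""


class EmptySetError(EwasMetaError):
    """A candidate set is empty after intersection with analysed probes."""


class InputError(EwasMetaError):
    """Numeric input violates a documented precondition (e.g. p outside (0,1])."""


class AnnotationError(EwasMetaError):
    """Probe or gene annotation is malformed (e.g. unknown chromosome label)."""
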