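"""Exception hierarchy for the epifit pipeline.

Every stage raises a subclass of :class:`EpifitError` so the CLI can map
user-facing problems to exit code 1 and anything else to exit code 2.
"""


class EpifitError(Exception):
    """Base class for all epifit errors."""


class SpecificationError(EpifitError):
    """A simulation spec or pipeline configuration is internally invalid."""


class ValidationError(EpifitError):
    """Input data violates a schema or value constraint (e.g. beta outside [0,1])."""


class AlignmentError(EpifitError):
    """Tables that must share sample IDs do not align."""


class DegenerateScaleError(EpifitError):
    """A column has zero variance where a scale is required."""


class CollinearityError(EpifitError):
    """A regression design matrix is rank deficient."""


class DegenerateWeightsError(EpifitError):
    """A CpG weight vector has zero norm and cannot define a projector."""


class UnresolvableProbeError(EpifitError):
    """A weighted CpG is absent from both the methylation matrix and the reference means."""


class ConfigurationError(EpifitError):
    """A required configuration entry (e.g. an expected direction) is missing."""
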