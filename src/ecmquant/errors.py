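"""Exception and warning types shared across the pipeline."""


class EcmQuantError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EcmQuantError, ValueError):
    """A parameter violates its documented domain."""


class InvalidInputError(EcmQuantError, ValueError):
    """An input image/table violates its invariants (non-finite pixels, ...)."""


class IncompatibleProfileError(EcmQuantError, ValueError):
    """Two angular profiles do not share the same angle grid."""


class DegenerateControlError(EcmQuantError, ValueError):
    """A control profile or control group cannot be used for normalization."""


class ContractViolationError(EcmQuantError, ValueError):
    """An operation was called on data that does not satisfy its contract
    (e.g. an alignment index requested on a raw, un-normalized profile)."""


class NoCellFoundError(EcmQuantError, ValueError):
    """Cell segmentation produced an empty foreground."""


class NoGelFoundError(EcmQuantError, ValueError):
    """Gel-silhouette segmentation produced an empty foreground."""


class CapacityError(EcmQuantError, ValueError):
    """Requested synthetic objects cannot be placed without overlap."""


class InsufficientDataError(EcmQuantError, ValueError):
    """A statistical group has too few observations."""


class ConfigValidationError(EcmQuantError, ValueError):
    """A pipeline configuration is malformed or references missing inputs."""


class FlatProfileWarning(UserWarning):
    """Emitted when a peak is requested on an all-equal angular profile."""


class NegativeContractionWarning(UserWarning):
    """Emitted when a follow-up gel area exceeds its baseline (gel swelled)."""


class EmptySegmentationWarning(UserWarning):
    """Emitted when a fixed threshold lies outside the intensity range so no
    objects can be segmented."""
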