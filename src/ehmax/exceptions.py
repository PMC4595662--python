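"""Exception hierarchy for the ehmax pipeline."""


class EHMaxError(Exception):
    """Base class for all ehmax errors."""


class ConfigError(EHMaxError):
    """A configuration value violates an invariant; the message names the field."""


class ParameterError(EHMaxError):
    """An operation received an invalid parameter."""


class DatasetLayoutError(EHMaxError):
    """The on-disk dataset does not follow the discovery/natural layout."""


class InsufficientDataError(EHMaxError):
    """Too few images or samples to carry out the requested operation."""


class SizeError(EHMaxError):
    """An input raster is too small for the requested filter or pooling window."""


class IncompleteInputError(EHMaxError):
    """A feature-map stack is missing a required scale or orientation."""


class EncodingError(EHMaxError):
    """C2 encoding could not be computed (e.g. no valid S2 map for a cluster)."""


class LearningFailureError(EHMaxError):
    """Prototype learning ended with zero surviving clusters."""
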