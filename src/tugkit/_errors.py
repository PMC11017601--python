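"""Exception hierarchy for the pipeline.

Each stage raises a typed error so the CLI can map failures onto stable exit
codes (config -> 2, data -> 3, segmentation -> 4).
"""


class TugkitError(Exception):
    """Base class for all package errors."""


class SchemaError(TugkitError):
    """A file does not conform to the documented CSV schema."""


class DataError(TugkitError):
    """Input data violate an invariant (non-monotonic time, short segment, ...)."""


class ParameterError(TugkitError, ValueError):
    """An argument is outside its valid domain."""


class ConfigError(TugkitError):
    """Configuration file or block is invalid (unknown key, bad enum value)."""


class SegmentationError(TugkitError):
    """Automatic event detection failed.

    Carries any partially detected events in ``partial_events`` for logging.
    """

    def __init__(self, message, partial_events=None):
        super().__init__(message)
        self.partial_events = partial_events
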