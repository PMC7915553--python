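"""Exception hierarchy shared across the package."""


class TrackemError(Exception):
    """Base class for package errors."""


class SchemaError(TrackemError):
    """Input file does not conform to the trajectory/config schema."""


class EstimationError(TrackemError):
    """A pipeline stage could not produce an estimate."""
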