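"""Exception hierarchy."""


class SCTrackError(Exception):
    """Base class for all package errors."""


class FormatError(SCTrackError):
    """Malformed or unsupported input data."""


class DegenerateContourError(SCTrackError):
    """A contour with fewer than 3 vertices or zero area."""


class OrderingError(SCTrackError):
    """Frame-ordering violation when growing a branch."""


class StateError(SCTrackError):
    """Operation attempted on a closed or otherwise invalid tree state."""


class ConfigurationError(SCTrackError):
    """Invalid or infeasible configuration."""
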