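"""Exception hierarchy shared across the toolkit.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class FgsKitError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(FgsKitError):
    """Invalid configuration: unknown keys, out-of-range parameters."""


class DataError(FgsKitError):
    """Invalid or inconsistent input data."""


class BehindCameraError(DataError):
    """A world point or target plane lies at non-positive depth."""


class DegenerateGeometryError(DataError):
    """Point configuration too degenerate for a projective fit."""


class MappingError(DataError):
    """A point maps to (or too near) the plane at infinity."""


class ParityAmbiguityError(DataError):
    """Laser on/off parity cannot be decided from frame statistics."""
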