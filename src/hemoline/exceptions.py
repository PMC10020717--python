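"""Exception hierarchy.

All package errors derive from :class:`HemolineError` so callers can catch
one base class at pipeline level.
"""


class HemolineError(Exception):
    """Base class for all hemoline errors."""


class ConfigurationError(HemolineError):
    """Invalid configuration (bad ranges, inconsistent sizes, empty grids)."""


class GeometryError(HemolineError):
    """Geometry construction or processing failed (self-intersection, degenerate tangent)."""


class PhysicsError(HemolineError):
    """Physically invalid input to the reduced-order solver (e.g. non-positive lumen area)."""


class InputError(HemolineError):
    """Malformed operation input (length mismatch, wrong width, non-positive rate)."""


class MissingDataError(HemolineError):
    """Required samples/sections/artifacts are absent."""


class TrainingError(HemolineError):
    """Model training diverged (NaN loss) or was misconfigured."""
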