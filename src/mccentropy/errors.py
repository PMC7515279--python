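"""Exception hierarchy.

All package errors derive from :class:`MCCError` so callers (and the CLI)
can distinguish configuration, input and numerical failures.
"""


class MCCError(Exception):
    """Base class for all package errors."""


class ConfigError(MCCError):
    """Invalid run configuration (temperature, flags, tolerances)."""


class TopologyError(MCCError):
    """Malformed molecular topology (bad bonds, hydrogens, indices)."""


class FormatError(MCCError):
    """Trajectory or topology file does not match its declared format."""


class UnusableInputError(MCCError):
    """Input is syntactically valid but missing required data (e.g. forces)."""


class InsufficientDataError(MCCError):
    """Too few samples to finalise an estimate."""


class GeometryError(MCCError):
    """Degenerate geometry (coincident points, zero inertia everywhere)."""
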