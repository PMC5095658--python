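"""Exception hierarchy shared across the package.

Config/usage errors derive from :class:`ConfigError`; problems with the
data itself (malformed files, impossible geometries, degenerate inputs)
derive from :class:`DataError`.  The CLI maps the two branches to
distinct exit codes.
"""


class ImcQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(ImcQuantError):
    """Invalid configuration or parameters."""


class DataError(ImcQuantError):
    """Invalid or inconsistent data."""


class PanelError(ConfigError):
    """Panel is missing required channels or roles."""


class RawFormatError(DataError):
    """Malformed raw transient-signal file."""


class GeometryError(DataError):
    """Scan geometry inconsistent with the data."""


class SimulationError(DataError):
    """Synthetic-tissue generation could not satisfy its targets."""


class FitError(DataError):
    """Histogram fitting failed on degenerate input."""
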