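"""Exception hierarchy.

All errors raised on invalid scientific inputs derive from
:class:`DataError` so the command-line layer can map them to a distinct
exit status; programming errors propagate as ordinary exceptions.
"""


class FluoriboError(Exception):
    """Base class for all package-specific errors."""


class DataError(FluoriboError, ValueError):
    """Invalid or degenerate input data (bad file, bad value, bad design)."""


class ConfigError(FluoriboError, ValueError):
    """Invalid pipeline configuration (missing files, bad parameter ranges)."""
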