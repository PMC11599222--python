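"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so shell callers can tell a
malformed config from bad data from an under-identified model.
"""


class MrError(Exception):
    """Base class for all mrmediate errors."""


class ConfigError(MrError):
    """Invalid or incomplete run configuration."""


class DataError(MrError):
    """Input summary statistics are missing, malformed, or empty after filtering."""


class IdentificationError(MrError):
    """The requested model cannot be identified from the available instruments."""
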