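"""Exception hierarchy."""


class HeatmirError(Exception):
    """Base class for all package errors."""


class FormatError(HeatmirError):
    """A file violates its declared format (bad token, duplicate id, shape)."""


class MetadataError(HeatmirError):
    """Sample metadata and expression data disagree."""


class ConfigError(HeatmirError):
    """Invalid configuration (unknown key, missing prerequisite, bad value)."""
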