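"""Exception hierarchy shared by all metawave modules."""


class MetawaveError(Exception):
    """Base class for all metawave errors."""


class InputError(MetawaveError):
    """Invalid user-supplied data (bad character, out-of-range parameter)."""


class FormatError(MetawaveError):
    """Malformed file content (FASTQ length mismatch, truncated MGDB, ...)."""


class ConfigError(MetawaveError):
    """Inconsistent configuration (e.g. profile mismatch between read and database)."""
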