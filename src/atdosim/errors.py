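"""Exception types shared across the pipeline."""


class AtdosimError(Exception):
    """Base class for all package errors."""


class ValidationError(AtdosimError, ValueError):
    """An input value violates a precondition (negative time, bad flag...)."""


class SchemaError(AtdosimError, ValueError):
    """A tabular input is structurally malformed (missing column, empty file)."""


class ConfigError(AtdosimError, ValueError):
    """A configuration entry is missing or inconsistent."""
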