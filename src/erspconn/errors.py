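"""Pipeline exception taxonomy mapped to CLI exit codes."""

__all__ = ["ConfigError", "DataError"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Unreadable or inconsistent input data (CLI exit code 3)."""
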