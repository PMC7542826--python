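"""Exception hierarchy shared across the package."""


class KaryoratesError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KaryoratesError):
    """A config/dialect problem: missing columns, bad fractions, bad settings."""


class DataError(KaryoratesError):
    """Invalid or inconsistent input data (trees, tip states, tables)."""
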