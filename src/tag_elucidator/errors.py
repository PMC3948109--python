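"""Exception hierarchy shared across the package.

CLI exit-code mapping: UsageError-style problems exit 1, DataError exits 2.
"""


class TagElucidatorError(Exception):
    """Base class for all package errors."""


class FormulaError(TagElucidatorError):
    """Malformed molecular formula string or invalid element count."""


class ConfigError(TagElucidatorError):
    """Invalid or inconsistent configuration (unknown element, bad cation...)."""


class DataError(TagElucidatorError):
    """Malformed or silently-corrupting input data (peak lists, tables)."""
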