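"""Exception hierarchy.

``ConfigError`` covers invalid configuration (exit code 2 in the CLI),
``DataError`` covers problems with the data themselves (exit code 3).
"""


class AdvesigError(Exception):
    """Base class for all package errors."""


class ConfigError(AdvesigError, ValueError):
    """Invalid configuration, thresholds, probabilities or usage."""


class DataError(AdvesigError, ValueError):
    """Malformed or degenerate input data."""


class SchemaError(DataError):
    """A mandatory column is missing from a line-listing file."""


class DegenerateTableError(DataError):
    """A 2x2 contingency table cell pattern makes the statistic undefined."""
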