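"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and its subclass
``ParseError``) to exit code 3.
"""


class ConfigError(Exception):
    """Invalid or inconsistent configuration / hyperparameters."""


class DataError(Exception):
    """Input data violates a precondition of the pipeline."""


class ParseError(DataError):
    """Malformed PLINK text input (bad column count, duplicate ids, ...)."""
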