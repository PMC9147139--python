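"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes (configuration vs. data
format vs. privacy).
"""


class HFScoresError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HFScoresError):
    """Invalid profile, pipeline config, or missing required path."""


class FormatError(HFScoresError):
    """A delimited-text file does not match the expected dialect."""


class RowParseError(FormatError):
    """A data row could not be parsed; carries the 1-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class SchemaError(HFScoresError):
    """A score-definition file violates the definition schema."""


class InvalidInputError(HFScoresError):
    """An operation received arguments outside its domain."""


class MissingInputError(InvalidInputError):
    """A required score variable is absent; carries the variable names."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__("missing required variables: " + ", ".join(self.missing))


class PrivacyError(HFScoresError):
    """An output would expose non-pseudonymized identifiers."""


class MergeError(HFScoresError):
    """Site result tables cannot be pooled (e.g. site-code collision)."""
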