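"""Exception and warning hierarchy for the idcard package."""


class IdCardError(Exception):
    """Base class for all idcard errors."""


class FeatureTableFormatError(IdCardError):
    """A feature-table CSV is malformed (missing columns, bad rows, empty file)."""


class CardSchemaError(IdCardError):
    """An identity-card document does not conform to the card schema."""


class ConfigurationError(IdCardError):
    """An operation was invoked with an invalid or incomplete configuration."""


class EmptyCardError(IdCardError):
    """Card building produced no ions; a card cannot be empty."""


class IdCardWarning(UserWarning):
    """Base class for idcard warnings (small cards, empty shared sets, ...)."""


class PreprocessingMismatchWarning(IdCardWarning):
    """A sample is matched against a card built under different preprocessing."""
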