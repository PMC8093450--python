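"""Exception hierarchy shared across the package."""


class CogloadError(Exception):
    """Base class for all package errors."""


class SchemaError(CogloadError):
    """A CSV recording does not match its declared schema."""


class DataError(CogloadError):
    """Well-formed file, invalid content (e.g. non-monotone timestamps)."""


class DegenerateInputError(CogloadError):
    """Input too small or too uniform for the operation to be defined."""


class EpochRejectedError(CogloadError):
    """An epoch failed quality gates (e.g. too few valid samples)."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ParameterError(CogloadError):
    """An analysis parameter is inconsistent with the data (e.g. cutoff >= Nyquist)."""
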