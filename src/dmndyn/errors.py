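"""Exception hierarchy shared across the pipeline."""


class DmndynError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DmndynError, ValueError):
    """A simulation or analysis configuration is internally inconsistent."""


class FormatError(DmndynError, ValueError):
    """An on-disk artifact does not match the expected file format."""


class SchemaError(DmndynError, ValueError):
    """A tabular input is missing required columns or violates a table invariant."""


class ValidationError(DmndynError, ValueError):
    """Input values violate a documented precondition."""


class ResponseExcluded(DmndynError):
    """A behavioral response is excluded from scoring (absence of thought, empty, OOV)."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)
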