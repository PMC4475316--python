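"""Exception hierarchy for the ecgqc package."""


class EcgQcError(Exception):
    """Base class for all ecgqc errors."""


class InputError(EcgQcError):
    """A file or argument is missing, unreadable, or structurally invalid."""


class FormatError(EcgQcError):
    """A file was found but its contents violate the expected format."""


class MissingLeadError(EcgQcError):
    """A required analysis lead is absent from a record."""

    def __init__(self, lead: str):
        self.lead = lead
        super().__init__(f"required lead {lead!r} is absent from the record")


class ConfigError(EcgQcError):
    """A generator or run configuration is invalid."""
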