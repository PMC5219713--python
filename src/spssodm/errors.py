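"""Exception hierarchy for the converter."""


class SpssOdmError(Exception):
    """Base class for all package errors."""


class InvalidDatasetError(SpssOdmError):
    """A dataset violates its structural invariants.

    Carries the list of :class:`~spssodm.report.Issue` records that
    describe each violation.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        msg = "; ".join(i.message for i in self.issues) or "invalid dataset"
        super().__init__(msg)


class InputFormatError(SpssOdmError):
    """An input file could not be read (unreadable, malformed, mismatched)."""


class SavBackendUnavailableError(SpssOdmError):
    """The binary .sav backend (pyreadstat) is not installed.

    The portable JSON-dictionary + CSV dialect needs no binary backend;
    use ``read_portable``/``write_portable`` instead.
    """


class SubjectKeyError(SpssOdmError):
    """The designated subject-key variable is missing or its keys collide."""


class LanguageTagError(SpssOdmError):
    """A language code does not match the RFC 3066 grammar."""

    def __init__(self, code: str):
        self.code = code
        super().__init__(f"invalid RFC 3066 language code: {code!r}")


class OdmStructureError(SpssOdmError):
    """An ODM model violates the structural rules needed for conversion."""


class ConversionError(SpssOdmError):
    """A value could not be converted (e.g. time-of-day out of range)."""
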