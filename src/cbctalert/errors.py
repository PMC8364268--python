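"""Exception hierarchy shared by all cbctalert modules."""


class CbctAlertError(Exception):
    """Base class for all package errors."""


class FormatError(CbctAlertError):
    """A file could not be read or written in the expected format.

    Raised for malformed DICOM series (missing slices, inconsistent
    spacing), bad sidecar metadata, unparseable transform files, etc.
    Mapped to exit code 2 by the CLI.
    """


class PreconditionError(CbctAlertError):
    """Inputs are well-formed but violate an operation's precondition.

    Examples: empty mask entering gamma evaluation, fewer than two usable
    CBCTs in a plan, a positive case without a re-CT fraction. Mapped to
    exit code 3 by the CLI.
    """
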