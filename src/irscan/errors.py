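"""Exception hierarchy."""


class IRScanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IRScanError):
    """An input file violates the expected text format."""


class InputError(IRScanError):
    """Inputs are individually valid but mutually inconsistent."""


class OracleGuardError(IRScanError):
    """The brute-force oracle was asked to scan a sequence beyond its size guard."""
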