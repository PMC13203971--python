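"""Exception hierarchy for viromarker."""


class ViromarkerError(Exception):
    """Base class for all viromarker errors."""


class FormatError(ViromarkerError):
    """A file could not be parsed: wrong columns, ragged rows, bad FASTA."""


class ValidationError(ViromarkerError):
    """Parsed content violates a domain invariant (range, uniqueness, ...)."""
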