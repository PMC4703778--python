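"""Exception hierarchy shared across the package."""


class PwConsensusError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PwConsensusError):
    """An input value or object violates a documented invariant."""


class ParseError(PwConsensusError):
    """A flat file could not be parsed; message names file and line."""
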