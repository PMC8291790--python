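"""Exception hierarchy shared across bridgeforge modules."""


class BridgeForgeError(Exception):
    """Base class for all bridgeforge errors."""


class ParseError(BridgeForgeError):
    """A file or token could not be parsed; the message names the offender."""


class ValidationError(BridgeForgeError):
    """Input violated a documented precondition or invariant."""
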