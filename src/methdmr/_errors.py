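"""Exception hierarchy shared by all pipeline stages."""


class MethdmrError(Exception):
    """Base class for all package errors."""


class ParseError(MethdmrError):
    """A file could not be parsed (column count, missing attribute, ...)."""


class ValidationError(MethdmrError):
    """Input violated a documented invariant (negative counts, bad labels, ...)."""


class ParameterError(MethdmrError):
    """A function argument is outside its valid range."""
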