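"""Exception hierarchy shared by all pipeline stages."""


class PhoscomplexError(Exception):
    """Base class for all package errors."""


class SchemaError(PhoscomplexError):
    """A table does not match its declared schema (e.g. missing column)."""


class ValidationError(PhoscomplexError):
    """A value violates a documented invariant (range, sign, monotonicity)."""


class StageError(PhoscomplexError):
    """A pipeline stage failed; the message names the stage."""
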