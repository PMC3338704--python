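"""Exception hierarchy."""


class CatresError(Exception):
    """Base class for all package errors."""


class FormatError(CatresError):
    """A file could not be parsed as the expected format."""


class ValidationError(CatresError):
    """Parsed or supplied data violates an invariant."""


class UnsupportedVersionError(FormatError):
    """A serialized model declares a format version this code cannot read."""
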