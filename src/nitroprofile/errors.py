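"""Exception hierarchy shared across the package."""


class NitroprofileError(Exception):
    """Base class for all package errors."""


class FormatError(NitroprofileError):
    """A table or string does not follow the expected format."""


class ValidationError(NitroprofileError):
    """A value violates a stated invariant (range, uniqueness, partition)."""
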