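"""Exception hierarchy shared across the toolkit."""


class NtcpKitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(NtcpKitError, ValueError):
    """Input data violates a structural invariant (e.g. non-monotone DVH)."""


class UndefinedValueError(NtcpKitError, ValueError):
    """A quantity is mathematically undefined for the given input
    (e.g. percent volume of a zero-volume structure)."""


class RangeError(NtcpKitError, ValueError):
    """A query parameter lies outside the valid domain."""


class ParseError(NtcpKitError, ValueError):
    """A DVH table or manifest file could not be parsed."""


class DegenerateSampleError(NtcpKitError, ValueError):
    """A statistical test has no information left (e.g. all paired
    differences are zero)."""
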