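"""Exception types shared across the package."""


class XenodissectError(Exception):
    """Base class for package errors."""


class InvalidParameterError(XenodissectError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(XenodissectError, ValueError):
    """An input object violates a documented precondition."""


class UndefinedCompositionError(XenodissectError, ValueError):
    """No classified reads remain after exclusions; composition is undefined."""


class UndefinedScoreError(XenodissectError, ValueError):
    """An enrichment score cannot be computed (e.g. no set member present)."""


class InvalidTriadError(XenodissectError, ValueError):
    """A triad is missing one of its three passage roles."""
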