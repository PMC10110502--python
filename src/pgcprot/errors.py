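"""Exception hierarchy shared by all pgcprot modules."""


class PgcprotError(Exception):
    """Base class for all package errors."""


class ParameterError(PgcprotError, ValueError):
    """A generator or analysis parameter is outside its physical domain."""


class InputError(PgcprotError, ValueError):
    """Input data violate a precondition (empty mask, too few points, ...)."""
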