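"""Exception hierarchy shared across the package."""


class MultipusError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MultipusError):
    """Malformed input: unknown identifiers, empty reactant lists, bad files."""


class InfeasibleInstanceError(MultipusError):
    """Raised by pre-solve reduction when a target is provably unproducible."""


class GuardrailError(MultipusError):
    """A search-space guardrail (tentacular count, terminal count, oracle size)
    was exceeded without an explicit override."""
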