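"""Exception hierarchy shared across the package."""


class NetspreadError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NetspreadError, ValueError):
    """An input object violates its structural invariants."""


class FormatError(NetspreadError, ValueError):
    """A file could not be parsed into a valid object."""


class ConfigurationError(NetspreadError, ValueError):
    """A simulation or reaction configuration is inconsistent."""


class BracketError(NetspreadError, ValueError):
    """An invasion-value bracket does not straddle the transition."""


class IntegrationError(NetspreadError, RuntimeError):
    """The numerical integrator produced an unusable state."""


class GenerationError(NetspreadError, RuntimeError):
    """The synthetic-connectome generator could not satisfy its constraints."""
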