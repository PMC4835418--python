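"""Exception hierarchy shared across the simulator."""


class OxiloopError(Exception):
    """Base class for all package errors."""


class ValidationError(OxiloopError, ValueError):
    """A physiological profile, artifact spec or record violates its constraints."""


class ConfigurationError(OxiloopError, ValueError):
    """A rate, filter or session parameter is unrealizable."""


class StreamCorruptionError(OxiloopError):
    """A multiplexed stream's slot labels do not follow the LED cycle."""


class InsufficientDataError(OxiloopError):
    """A window is too short for the requested decision or estimate."""


class ProtocolError(OxiloopError):
    """Records arrived out of time order on the controller side."""


class ParseError(OxiloopError):
    """A log or config file does not match its documented schema."""
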