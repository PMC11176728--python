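"""Exception types shared across the package."""


class PollensizeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PollensizeError, ValueError):
    """An argument violates an operation's preconditions."""


class MaskFormatError(PollensizeError, ValueError):
    """A mask file could not be decoded to a 2-D raster."""


class SceneSizeError(PollensizeError, ValueError):
    """The requested canvas is too small for the requested scene content."""


class GateError(PollensizeError, ValueError):
    """A sample failed a configured count gate."""


class UnsupportedError(PollensizeError, ValueError):
    """A requested configuration is outside the supported range."""


class MetricMismatchError(PollensizeError, ValueError):
    """Measurement and reference tables use different size metrics."""
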