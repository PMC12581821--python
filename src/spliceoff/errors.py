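"""Exception hierarchy shared across the package."""


class SpliceoffError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpliceoffError):
    """An input file violates its declared dialect."""


class BoundsError(SpliceoffError):
    """A coordinate or interval falls outside its container."""


class ConfigurationError(SpliceoffError):
    """A configuration value is missing, inconsistent or unusable."""


class GenerationError(SpliceoffError):
    """The synthetic-data generator could not satisfy the scenario."""


class AmbiguityError(SpliceoffError):
    """More than one candidate matched where exactly one was required."""
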