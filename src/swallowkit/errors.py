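"""Exception hierarchy for swallowkit.

All package-specific failures derive from :class:`SwallowKitError` so callers
can catch one base class at pipeline level while tests assert precise types.
"""


class SwallowKitError(Exception):
    """Base class for all swallowkit errors."""


class FormatError(SwallowKitError):
    """A file does not conform to the expected on-disk layout."""


class NamingError(SwallowKitError):
    """A channel name is not one of the recognised transducer channels."""


class SamplingError(SwallowKitError):
    """A time column is non-uniform or inconsistent with the stated rate."""


class ParameterError(SwallowKitError):
    """An argument is outside its valid domain (unstable AR poles, bad knots...)."""


class DegenerateSignalError(SwallowKitError):
    """A signal lacks the variation an operation requires (constant, all-zero)."""


class ConfigurationError(SwallowKitError):
    """Required channels/models/config entries are missing or inconsistent."""


class PairingError(SwallowKitError):
    """Feature rows cannot be paired across channels for a paired test."""
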