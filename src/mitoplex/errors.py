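"""Exception hierarchy."""


class MitoplexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MitoplexError):
    """Invalid configuration value or combination."""


class NoSignalError(MitoplexError):
    """A reference cube contains no usable signal."""


class CollinearLibraryError(MitoplexError):
    """Spectral library is rank deficient."""

    def __init__(self, pair: tuple[str, str]):
        self.pair = pair
        super().__init__(
            f"spectral library is rank deficient: endmembers {pair[0]!r} and "
            f"{pair[1]!r} are collinear"
        )


class InsufficientControlsError(MitoplexError):
    """Fewer control cells than the configured minimum."""


class DegenerateModelError(MitoplexError):
    """Control model has (near) zero spread and cannot produce Z-scores."""
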