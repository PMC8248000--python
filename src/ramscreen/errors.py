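"""Exception hierarchy shared across the package."""


class RamscreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RamscreenError, ValueError):
    """Invalid domain values (compositions, thresholds, config)."""


class FormatError(RamscreenError, ValueError):
    """Malformed or unsupported on-disk spectrum data."""


class UsageError(RamscreenError, ValueError):
    """A call that is wrong regardless of the data (bad flag, bad window)."""


class RangeError(RamscreenError, ValueError):
    """A request outside the supported wavenumber/data range."""


class DegenerateInputError(RamscreenError, ValueError):
    """Input that makes the operation mathematically undefined."""


class RankError(RamscreenError, ValueError):
    """More latent components requested than the data can support."""
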