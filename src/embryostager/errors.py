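"""Exception hierarchy for the embryostager pipelines."""


class EmbryoStagerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EmbryoStagerError, ValueError):
    """A parameter or spec violates a documented invariant."""


class DegenerateHistogramError(EmbryoStagerError, ValueError):
    """Raised when a global threshold is requested on a constant image."""


class EmptyMaskError(EmbryoStagerError, ValueError):
    """Raised when an operation needs at least one foreground pixel."""


class NoMarkersError(EmbryoStagerError, ValueError):
    """Raised when a seeded flood is started without any usable seed."""


class EmbryoNotFoundError(EmbryoStagerError, ValueError):
    """Raised when segmentation of a frame yields no embryo object."""
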