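"""Exception hierarchy for spatialepi."""


class SpatialEpiError(Exception):
    """Base class for all package errors."""


class FormatError(SpatialEpiError):
    """A file does not conform to its declared format."""


class AlignmentError(SpatialEpiError):
    """Spatial frame and attribute table ids do not match."""


class DegenerateInputError(SpatialEpiError):
    """Input is statistically degenerate (e.g. constant variable, all-island W)."""


class CollinearityError(SpatialEpiError):
    """Design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = list(columns)


class ConvergenceError(SpatialEpiError):
    """Optimizer failed to converge to an interior optimum."""


class ConfigError(SpatialEpiError):
    """Pipeline configuration is invalid."""
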