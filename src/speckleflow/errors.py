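"""Exception types shared across the package."""


class SpeckleflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(SpeckleflowError, ValueError):
    """A simulation or run configuration violates its invariants."""


class DegenerateInputError(SpeckleflowError, ValueError):
    """Input is formally valid but the requested statistic is undefined
    (e.g. zero-variance image for a normalized autocovariance)."""


class FrontDetectionError(SpeckleflowError, RuntimeError):
    """The blood front could not be located or never crosses the ROI."""


class FormatError(SpeckleflowError, ValueError):
    """An input file does not match the expected on-disk format."""
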