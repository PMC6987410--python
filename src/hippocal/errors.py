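"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class FormatError(IOError):
    """A file could not be read or written in the expected format."""


class BaselineError(ValueError):
    """Baseline fluorescence is non-positive; dF/F is undefined."""


class UndefinedContrastError(ValueError):
    """Nuclear mean is non-positive; contrast is undefined."""


class DegenerateSampleError(ValueError):
    """A statistical test received a sample with no variability."""
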