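"""Exception and warning types shared across the package."""


class StripeSimError(Exception):
    """Base class for all stripesim errors."""


class InvalidArgumentError(StripeSimError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(StripeSimError, ValueError):
    """An input file does not have the expected layout or content."""


class ConfigError(StripeSimError, ValueError):
    """A configuration file is invalid (unknown or missing keys, bad values)."""


class NoPeakError(StripeSimError, RuntimeError):
    """No modulation peak could be located in the masked spectrum."""


class UndefinedPhaseError(StripeSimError, RuntimeError):
    """The spectrum value at the requested peak is zero; its phase is undefined."""


class SingularMatrixError(StripeSimError, ValueError):
    """The band-separation matrix is singular (duplicate phases or m = 0)."""


class DegenerateInputError(StripeSimError, ValueError):
    """The input is degenerate for the requested operation (e.g. constant reference)."""


class NotRegisteredError(StripeSimError, KeyError):
    """Requested element-wise operation or backend is not in the registry."""


class NonRepresentablePhaseWarning(UserWarning):
    """A requested stripe phase is not an integer pixel shift and was rounded."""


class NyquistWarning(UserWarning):
    """The sampling does not satisfy the Nyquist condition for the optical cutoff."""


class RefinementWarning(UserWarning):
    """Sub-pixel frequency refinement diverged and fell back to the coarse peak."""


class DataQualityWarning(UserWarning):
    """Input data required clipping or renormalisation (e.g. negative OTF values)."""
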