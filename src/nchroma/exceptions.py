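"""Exception and warning types shared across the package."""


class NchromaError(ValueError):
    """Base class for all package-specific errors."""


class SpectrumFormatError(NchromaError):
    """Malformed spectral table: non-numeric cells or non-increasing wavelengths."""


class SpectrumRangeError(NchromaError):
    """Requested wavelengths fall outside the measured range (no extrapolation)."""


class GridMismatchError(NchromaError):
    """Spectra that must share a wavelength grid do not."""


class DegenerateBackgroundError(NchromaError):
    """A background quantum catch is zero or negative; von Kries adaptation undefined."""


class TransformDomainError(NchromaError):
    """A photoreceptor transform was applied outside its domain (e.g. ln of q <= 0)."""


class RelativeOutputError(NchromaError):
    """Relative photoreceptor outputs undefined: the output sum is exactly zero."""


class ModelConfigError(NchromaError):
    """Inconsistent model configuration (e.g. a receptor-noise model without noise)."""


class NearSingularWarning(UserWarning):
    """The photoreceptor output sum is close to zero; relative outputs are unstable.

    Emitted rather than raised: the spurious large values this regime
    produces are a documented model behaviour that must propagate.
    """
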