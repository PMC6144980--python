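"""Color vision models over the generic n-dimensional chromaticity space.

Four named models share one pipeline — quantum catch, von Kries
adaptation, an input-output transform, projection through the basis
matrix V — and differ only in configuration:

=============  ==========  ================  ====================  ======
model          transform   relative outputs  space scaling         noise
=============  ==========  ================  ====================  ======
color hexagon  q/(q+1)     no                vector length 1       no
Endler-Mielke  ln          yes (sum to 1)    vector length 0.75    no
linear RNL     identity    no                (distance is          yes
log RNL        ln          no                noise-defined)        yes
=============  ==========  ================  ====================  ======

Receptor-noise-limited (RNL) distances are computed two ways: the
classical closed forms for di-, tri- and tetrachromats, and the generic
noise-space transform s = (V·R·Vᵀ)^(−1/2)·x valid for any number of
receptor types, where R is the diagonal matrix of receptor output
variances e_i². The two routes agree to numerical precision; the noise
space additionally gives plottable coordinates in which Euclidean
distance *is* the noise-weighted ΔS (units of just-noticeable
differences under the calibrating conditions).

A fifth, generic kind accepts any transform / scaling / noise
combination, so user-defined models (e.g. an RNL model with a
hyperbolic front end) need no new code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ModelConfigError, NearSingularWarning
from .geometry import ChromaticityBasis, chromaticity_basis, color_locus, euclidean_delta_s
from .photon_catch import (
    CatchVector,
    PhotoreceptorSet,
    em_relative,
    quantum_catch,
    relative_catch,
    transform_output,
)
from .spectra import Spectrum

__all__ = [
    "ModelConfig",
    "ModelResult",
    "run_model",
    "rnl_delta_s_closed",
    "rnl_noise_space",
    "rnl_delta_s_generic",
]

MODEL_KINDS = ("CH", "EM", "RNL_linear", "RNL_log", "generic")


@dataclass(frozen=True)
class ModelConfig:
    """Configuration resolving a model kind to pipeline settings.

    Use the factory classmethods (:meth:`ch`, :meth:`em`,
    :meth:`rnl_linear`, :meth:`rnl_log`, :meth:`generic`) rather than the
    raw constructor; they enforce each named model's conventions.
    """

    kind: str = "generic"
    transform: str = "identity"
    relative_outputs: bool = False
    scale_mode: str = "vector_length"
    scale_value: float = 1.0
    use_noise: bool = False
    noise: tuple[float, ...] | None = None
    custom_transform: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ModelConfigError(f"unknown model kind {self.kind!r}")
        if self.use_noise and self.noise is None:
            raise ModelConfigError(
                f"{self.kind} is a receptor-noise model: provide noise values "
                "(per-receptor Weber fractions)"
            )
        if not self.use_noise and self.noise is not None:
            raise ModelConfigError(
                f"{self.kind} does not use receptor noise; drop the noise values"
            )
        if self.noise is not None:
            noise = tuple(float(e) for e in self.noise)
            if any(e <= 0 for e in noise):
                raise ModelConfigError("noise values must be strictly positive")
            object.__setattr__(self, "noise", noise)
        if self.transform == "custom" and self.custom_transform is None:
            raise ModelConfigError("transform='custom' requires custom_transform")

    @classmethod
    def ch(cls) -> "ModelConfig":
        """Color hexagon: hyperbolic transform, unit receptor vectors, no noise."""
        return cls(kind="CH", transform="hyperbolic", scale_value=1.0)

    @classmethod
    def em(cls) -> "ModelConfig":
        """Endler-Mielke: ln transform, relative (sum-to-1) outputs, length 0.75."""
        return cls(kind="EM", transform="ln", relative_outputs=True, scale_value=0.75)

    @classmethod
    def rnl_linear(cls, noise: Sequence[float] | float) -> "ModelConfig":
        """Linear receptor-noise-limited model (valid for similar colors)."""
        return cls(kind="RNL_linear", transform="identity", use_noise=True,
                   noise=_as_noise(noise))

    @classmethod
    def rnl_log(cls, noise: Sequence[float] | float) -> "ModelConfig":
        """Log (Fechner-Weber) receptor-noise-limited model."""
        return cls(kind="RNL_log", transform="ln", use_noise=True, noise=_as_noise(noise))

    @classmethod
    def generic(
        cls,
        transform: str = "identity",
        relative_outputs: bool = False,
        scale_mode: str = "vector_length",
        scale_value: float = 1.0,
        noise: Sequence[float] | float | None = None,
        custom_transform: Callable[[np.ndarray], np.ndarray] | None = None,
    ) -> "ModelConfig":
        """A user-defined model from any transform/scaling/noise combination."""
        return cls(
            kind="generic",
            transform=transform,
            relative_outputs=relative_outputs,
            scale_mode=scale_mode,
            scale_value=scale_value,
            use_noise=noise is not None,
            noise=_as_noise(noise) if noise is not None else None,
            custom_transform=custom_transform,
        )

    def resolved_noise(self, i: int) -> tuple[float, ...]:
        noise = self.noise
        assert noise is not None
        if len(noise) == 1 and i > 1:
            return noise * i
        if len(noise) != i:
            raise ModelConfigError(f"{len(noise)} noise values for {i} receptors")
        return noise


def _as_noise(noise: Sequence[float] | float) -> tuple[float, ...]:
    if np.isscalar(noise):
        return (float(noise),)  # broadcast to receptor count at run time
    return tuple(float(e) for e in noise)  # type: ignore[union-attr]


@dataclass(frozen=True)
class ModelResult:
    """Everything a model computes for one stimulus.

    ``outputs`` is the vector p actually projected through V (relative
    outputs for Endler-Mielke, raw transformed outputs otherwise).
    ``delta_s_background`` is |locus| for the geometric models and the
    noise-weighted distance for RNL models (in which case ``noise_locus``
    holds coordinates whose Euclidean norm equals it). Warnings collected
    along the pipeline (near-singular relative outputs, negative
    log-transformed outputs) ride along as data.
    """

    name: str
    catch: CatchVector
    outputs: np.ndarray
    locus: np.ndarray
    delta_s_background: float
    basis: ChromaticityBasis
    config: ModelConfig
    noise_locus: np.ndarray | None = None
    warnings: tuple[str, ...] = ()


def run_model(
    stimulus: Spectrum,
    background: Spectrum,
    illuminant: Spectrum,
    receptors: PhotoreceptorSet,
    config: ModelConfig,
    basis: ChromaticityBasis | None = None,
) -> ModelResult:
    """Run one stimulus through the full model pipeline.

    Q → q (von Kries against ``background``) → E (configured transform)
    → optional relative outputs → locus = V·p → ΔS to the background.
    Spurious regimes (near-zero output sums under relative outputs,
    negative log outputs) propagate with warnings recorded on the result
    rather than being sanitized.
    """
    i = receptors.n_receptors
    if basis is None:
        basis = chromaticity_basis(i, config.scale_mode, config.scale_value)
    elif basis.i != i:
        raise ModelConfigError(f"basis is for {basis.i} receptors, set has {i}")

    Q_stim = quantum_catch(stimulus, illuminant, receptors)
    Q_bg = quantum_catch(background, illuminant, receptors)
    q = relative_catch(Q_stim, Q_bg)
    E = transform_output(q, config.transform, config.custom_transform)
    notes: list[str] = []
    if config.transform == "ln" and np.any(E < 0):
        notes.append(
            "negative log-transformed outputs (stimulus catch below background)"
        )

    if config.relative_outputs:
        if np.ptp(E) == 0.0:
            # all outputs identical (e.g. stimulus == background gives E = 0
            # elementwise): the stimulus sits at the simplex centre by
            # continuity, where E_i/sum(E) is 0/0
            p = np.full(i, 1.0 / i)
        else:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", NearSingularWarning)
                p = em_relative(E)
            for w in caught:
                if issubclass(w.category, NearSingularWarning):
                    notes.append(str(w.message))
    else:
        p = E

    locus = color_locus(basis, p)
    noise_locus = None
    if config.use_noise:
        noise = np.asarray(config.resolved_noise(i), dtype=float)
        E_bg = transform_output(np.ones(i), config.transform, config.custom_transform)
        delta_f = E - E_bg
        noise_locus = rnl_noise_space(basis, noise, basis.V @ delta_f)
        delta_s = float(np.linalg.norm(noise_locus))
    else:
        delta_s = euclidean_delta_s(locus)

    return ModelResult(
        name=stimulus.name,
        catch=CatchVector(Q=Q_stim, q=q, E=E),
        outputs=p,
        locus=locus,
        delta_s_background=delta_s,
        basis=basis,
        config=config,
        noise_locus=noise_locus,
        warnings=tuple(notes),
    )


# ---------------------------------------------------------------------------
# receptor-noise-limited distances


def rnl_delta_s_closed(
    E_a: Sequence[float], E_b: Sequence[float], noise: Sequence[float]
) -> float:
    """Closed-form receptor-noise-limited ΔS for 2, 3 or 4 receptor types.

    Δf_i = E_a,i − E_b,i. The classical formulas weight opponent
    differences by the channel Weber fractions e_i:

    - dichromat:  ΔS = |Δf₁ − Δf₂| / sqrt(e₁² + e₂²)
    - trichromat: ΔS² = (e₁²(Δf₃−Δf₂)² + e₂²(Δf₃−Δf₁)² + e₃²(Δf₂−Δf₁)²)
      / ((e₁e₂)² + (e₁e₃)² + (e₂e₃)²)
    - tetrachromat: the analogous ratio with products of two noise terms
      in the numerator and of three in the denominator.

    For more receptor types use :func:`rnl_delta_s_generic`.
    """
    f = np.asarray(E_a, dtype=float) - np.asarray(E_b, dtype=float)
    e = np.asarray(noise, dtype=float)
    if f.shape != e.shape:
        raise ValueError(f"outputs and noise disagree: {f.shape} vs {e.shape}")
    if np.any(e <= 0):
        raise ValueError("noise values must be strictly positive")
    i = f.size
    if i == 2:
        return float(abs(f[0] - f[1]) / np.sqrt(e[0] ** 2 + e[1] ** 2))
    if i == 3:
        num = (
            e[0] ** 2 * (f[2] - f[1]) ** 2
            + e[1] ** 2 * (f[2] - f[0]) ** 2
            + e[2] ** 2 * (f[1] - f[0]) ** 2
        )
        den = (e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2
        return float(np.sqrt(num / den))
    if i == 4:
        num = (
            (e[0] * e[1]) ** 2 * (f[3] - f[2]) ** 2
            + (e[0] * e[2]) ** 2 * (f[3] - f[1]) ** 2
            + (e[0] * e[3]) ** 2 * (f[2] - f[1]) ** 2
            + (e[1] * e[2]) ** 2 * (f[3] - f[0]) ** 2
            + (e[1] * e[3]) ** 2 * (f[2] - f[0]) ** 2
            + (e[2] * e[3]) ** 2 * (f[1] - f[0]) ** 2
        )
        den = (
            (e[0] * e[1] * e[2]) ** 2
            + (e[0] * e[1] * e[3]) ** 2
            + (e[0] * e[2] * e[3]) ** 2
            + (e[1] * e[2] * e[3]) ** 2
        )
        return float(np.sqrt(num / den))
    raise ValueError(
        f"closed forms exist for 2-4 receptor types (got {i}); "
        "use rnl_delta_s_generic"
    )


def _spd_inverse_sqrt(M: np.ndarray) -> np.ndarray:
    """Inverse symmetric square root of a symmetric positive-definite matrix."""
    eigval, eigvec = np.linalg.eigh(M)
    if eigval.min() <= 1e-14 * max(eigval.max(), 1.0):
        raise np.linalg.LinAlgError(
            "noise covariance in chromaticity coordinates is singular"
        )
    return (eigvec / np.sqrt(eigval)) @ eigvec.T


def rnl_noise_space(
    basis: ChromaticityBasis, noise: Sequence[float], x: Sequence[float]
) -> np.ndarray:
    """Map a color locus into receptor-noise units: s = (V·R·Vᵀ)^(−1/2)·x.

    R = diag(e_i²) is the (diagonal) covariance of photoreceptor outputs.
    V·R·Vᵀ is that covariance expressed in chromaticity coordinates;
    whitening by its inverse symmetric square root yields coordinates in
    which the Euclidean norm of s equals the receptor-noise-limited ΔS —
    distances, not squared distances, so the space is directly
    plottable. ``x`` must be a locus computed with the same basis; the
    basis scale cancels.
    """
    e = np.asarray(noise, dtype=float)
    if e.shape != (basis.i,):
        raise ValueError(f"{e.size} noise values for a {basis.i}-receptor basis")
    if np.any(e <= 0):
        raise ValueError("noise values must be strictly positive")
    x = np.asarray(x, dtype=float)
    if x.shape != (basis.n,):
        raise ValueError(f"locus has shape {x.shape}; basis expects ({basis.n},)")
    R = np.diag(e**2)
    W = basis.V @ R @ basis.V.T
    return _spd_inverse_sqrt(W) @ x


def rnl_delta_s_generic(
    E_a: Sequence[float],
    E_b: Sequence[float],
    noise: Sequence[float],
    basis: ChromaticityBasis | None = None,
) -> float:
    """Receptor-noise-limited ΔS for any number of receptor types.

    Computed as |s| with s the noise-space image of the locus of
    Δf = E_a − E_b. Agrees with :func:`rnl_delta_s_closed` for 2-4
    receptors to numerical precision and extends the model to penta-
    chromats and beyond.
    """
    f = np.asarray(E_a, dtype=float) - np.asarray(E_b, dtype=float)
    e = np.asarray(noise, dtype=float)
    if f.shape != e.shape:
        raise ValueError(f"outputs and noise disagree: {f.shape} vs {e.shape}")
    if basis is None:
        basis = chromaticity_basis(f.size)
    elif basis.i != f.size:
        raise ValueError(f"basis is for {basis.i} receptors, outputs have {f.size}")
    s = rnl_noise_space(basis, e, basis.V @ f)
    return float(np.linalg.norm(s))
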