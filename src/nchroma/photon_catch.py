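"""Quantum catches, von Kries adaptation, and photoreceptor transforms.

The front end shared by every color vision model: each receptor class i
integrates stimulus reflectance x illuminant x sensitivity over
wavelength (the quantum catch Q_i), is normalized by its catch from the
adapting background (von Kries adaptation, q_i = Q_i / Q_Bi), and is
passed through a model-specific input-output transform (identity, ln, or
the hyperbolic q/(q+1)) to give the photoreceptor output E_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import (
    DegenerateBackgroundError,
    GridMismatchError,
    NearSingularWarning,
    RelativeOutputError,
    TransformDomainError,
)
from .spectra import Spectrum, gaussian_sensitivity, pigment_template

__all__ = [
    "PhotoreceptorSet",
    "CatchVector",
    "quantum_catch",
    "relative_catch",
    "transform_output",
    "em_relative",
    "noise_from_abundance",
    "honeybee_like_receptors",
]

TRANSFORMS = ("identity", "ln", "hyperbolic", "custom")


@dataclass(frozen=True)
class PhotoreceptorSet:
    """An ordered set of photoreceptor sensitivity curves with optional noise.

    Receptors are ordered short to long peak wavelength. ``noise`` holds
    the per-receptor Weber fractions e_i required by receptor-noise-
    limited models (e.g. the honeybee's 0.13, 0.06, 0.12 for its S, M,
    L receptors); models that ignore noise may leave it unset.
    """

    sensitivities: tuple[Spectrum, ...]
    noise: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        sens = tuple(self.sensitivities)
        if len(sens) < 2:
            raise ValueError("need at least two photoreceptor types")
        for s in sens[1:]:
            if not sens[0].same_grid(s):
                raise GridMismatchError(
                    f"sensitivity {s.name!r} not on the shared wavelength grid"
                )
        object.__setattr__(self, "sensitivities", sens)
        if self.noise is not None:
            noise = tuple(float(e) for e in self.noise)
            if len(noise) != len(sens):
                raise ValueError(
                    f"{len(noise)} noise values for {len(sens)} receptors"
                )
            if any(e <= 0 for e in noise):
                raise ValueError("receptor noise values must be strictly positive")
            object.__setattr__(self, "noise", noise)

    @property
    def n_receptors(self) -> int:
        return len(self.sensitivities)

    @property
    def grid(self) -> np.ndarray:
        return self.sensitivities[0].wavelengths

    @property
    def noise_array(self) -> np.ndarray:
        if self.noise is None:
            raise ValueError("this photoreceptor set carries no noise values")
        return np.asarray(self.noise, dtype=float)

    @classmethod
    def from_gaussians(
        cls,
        peaks: Sequence[float],
        sd: float = 50.0,
        grid: Sequence[float] | None = None,
        noise: Sequence[float] | float | None = None,
    ) -> "PhotoreceptorSet":
        """Build a set of unit-peak Gaussian sensitivities at ``peaks`` (nm)."""
        sens = tuple(gaussian_sensitivity(p, sd=sd, grid=grid) for p in sorted(peaks))
        return cls(sens, _broadcast_noise(noise, len(sens)))

    @classmethod
    def from_templates(
        cls,
        peaks: Sequence[float],
        grid: Sequence[float] | None = None,
        noise: Sequence[float] | float | None = None,
    ) -> "PhotoreceptorSet":
        """Build a set from the A1 visual-pigment template at ``peaks`` (nm)."""
        sens = tuple(pigment_template(p, grid=grid) for p in sorted(peaks))
        return cls(sens, _broadcast_noise(noise, len(sens)))


def _broadcast_noise(
    noise: Sequence[float] | float | None, n: int
) -> tuple[float, ...] | None:
    if noise is None:
        return None
    if np.isscalar(noise):
        return (float(noise),) * n
    return tuple(float(e) for e in noise)  # type: ignore[union-attr]


def honeybee_like_receptors(
    grid: Sequence[float] | None = None,
    noise: Sequence[float] = (0.13, 0.06, 0.12),
) -> PhotoreceptorSet:
    """Synthetic honeybee-like trichromat (λmax 344, 436, 544 nm).

    Pigment-template stand-in for measured *Apis mellifera* sensitivity
    curves, with the standard S/M/L Weber-fraction noise (0.13, 0.06,
    0.12). Quantitative results from the real curves differ; load those
    from CSV for faithful honeybee modelling.
    """
    return PhotoreceptorSet.from_templates((344.0, 436.0, 544.0), grid=grid, noise=noise)


@dataclass(frozen=True)
class CatchVector:
    """Per-receptor quantities for one stimulus.

    Q: absolute quantum catches; q: catches relative to the background
    (von Kries); E: transformed photoreceptor outputs.
    """

    Q: np.ndarray
    q: np.ndarray
    E: np.ndarray


def quantum_catch(
    reflectance: Spectrum,
    illuminant: Spectrum,
    receptors: PhotoreceptorSet,
) -> np.ndarray:
    """Quantum catch Q_i per receptor: ∫ R(λ)·I(λ)·S_i(λ) dλ.

    Trapezoidal integration on the shared grid — exact for the
    piecewise-linear representation produced by resampling. All three
    spectral inputs must share the receptor set's grid.
    """
    if not reflectance.same_grid(illuminant):
        raise GridMismatchError("reflectance and illuminant grids differ")
    if not reflectance.same_grid(receptors.sensitivities[0]):
        raise GridMismatchError("stimulus and receptor sensitivity grids differ")
    wl = reflectance.wavelengths
    product = reflectance.values * illuminant.values
    return np.array(
        [np.trapezoid(product * s.values, wl) for s in receptors.sensitivities]
    )


def relative_catch(Q_stimulus: np.ndarray, Q_background: np.ndarray) -> np.ndarray:
    """von Kries adaptation: q_i = Q_i / Q_Bi; the background maps to q = 1."""
    Q = np.asarray(Q_stimulus, dtype=float)
    Qb = np.asarray(Q_background, dtype=float)
    if Q.shape != Qb.shape:
        raise ValueError(f"shape mismatch: {Q.shape} vs {Qb.shape}")
    if np.any(Qb <= 0):
        bad = int(np.argmax(Qb <= 0))
        raise DegenerateBackgroundError(
            f"background quantum catch of receptor {bad + 1} is {Qb[bad]:g}; "
            "von Kries adaptation needs strictly positive background catches"
        )
    return Q / Qb


def transform_output(
    q: np.ndarray,
    kind: str = "identity",
    custom: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Photoreceptor input-output transform E = f(q).

    identity — linear response (valid near the adaptation point only);
    ln — Fechner-Weber logarithmic response, E = ln(q), negative for
    q < 1; hyperbolic — saturating response E = q/(q+1), bounded in
    [0, 1); custom — any elementwise callable.
    """
    q = np.asarray(q, dtype=float)
    if kind == "identity":
        return q.copy()
    if kind == "ln":
        if np.any(q <= 0):
            bad = int(np.argmax(q <= 0))
            raise TransformDomainError(
                f"ln transform undefined: receptor {bad + 1} has relative catch "
                f"{q[bad]:g} <= 0"
            )
        return np.log(q)
    if kind == "hyperbolic":
        if np.any(q < 0):
            raise TransformDomainError("hyperbolic transform needs q >= 0")
        return q / (q + 1.0)
    if kind == "custom":
        if custom is None:
            raise ValueError("kind='custom' requires a callable")
        E = np.asarray(custom(q), dtype=float)
        if E.shape != q.shape:
            raise TransformDomainError("custom transform changed the vector shape")
        if not np.all(np.isfinite(E)):
            bad = int(np.argmax(~np.isfinite(E)))
            raise TransformDomainError(
                f"custom transform returned non-finite output for receptor {bad + 1}"
            )
        return E
    raise ValueError(f"unknown transform {kind!r}; expected one of {TRANSFORMS}")


def em_relative(E: np.ndarray, tolerance: float = 1e-8) -> np.ndarray:
    """Relative photoreceptor outputs e_i = E_i / Σ_j E_j.

    Color opponency is assumed to read only relative output differences,
    so outputs are projected onto the unit-sum simplex. When the output
    sum approaches zero the components blow up — a documented spurious
    regime that is deliberately passed through, flagged with
    :class:`NearSingularWarning`. An exactly zero sum is an error.
    """
    E = np.asarray(E, dtype=float)
    total = float(E.sum())
    if total == 0.0:
        raise RelativeOutputError(
            "photoreceptor outputs sum to exactly zero; relative outputs undefined"
        )
    if abs(total) < tolerance:
        warnings.warn(
            f"photoreceptor output sum {total:.3e} is near zero; relative outputs "
            "are numerically unstable and may be spuriously large",
            NearSingularWarning,
            stacklevel=2,
        )
    return E / total


def noise_from_abundance(
    single_cell_noise: float, abundances: Sequence[float]
) -> tuple[float, ...]:
    """Channel Weber fractions from relative receptor abundances: e_i = ν/√η_i.

    Convenience following the standard receptor-noise literature: channel
    noise falls with the square root of the number of pooled receptors.
    ``abundances`` are relative counts (any positive scale).
    """
    if single_cell_noise <= 0:
        raise ValueError("single-cell noise must be positive")
    eta = np.asarray(abundances, dtype=float)
    if np.any(eta <= 0):
        raise ValueError("abundances must be strictly positive")
    return tuple(single_cell_noise / np.sqrt(eta))
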