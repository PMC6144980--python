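"""Spectral inputs: containers, readers, resampling, and synthetic generators.

Everything a color vision model consumes is a spectrum on a common
wavelength grid: stimulus and background reflectances (fractions of
incident light), the illuminant (relative photon flux / spectral power),
and photoreceptor sensitivity curves. This module provides an immutable
:class:`Spectrum`, a :class:`SpectralLibrary` that harmonizes a set of
spectra onto one grid, CSV I/O, and the synthetic generators used by the
simulation harnesses (flat, logistic and Gaussian reflectances, Gaussian
and visual-pigment-template sensitivities, a packaged D65 illuminant, and
a leaf-like chromatic background).

The canonical internal unit for reflectance is the fraction (0-1);
percent input is converted at read time. The default working grid is
300-700 nm at 1-nm steps, the range relevant to UV-sensitive insect and
avian vision. No function ever extrapolates outside the measured range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import SpectrumFormatError, SpectrumRangeError

__all__ = [
    "Spectrum",
    "SpectralLibrary",
    "default_grid",
    "read_spectrum_table",
    "resample",
    "clamp_nonnegative",
    "flat_reflectance",
    "logistic_reflectance",
    "gaussian_reflectance",
    "shift_reflectance",
    "gaussian_sensitivity",
    "pigment_template",
    "builtin_illuminant",
    "leaf_background",
    "synthetic_flora",
]

KINDS = ("reflectance", "illuminant", "sensitivity")


def default_grid(start: float = 300.0, stop: float = 700.0, step: float = 1.0) -> np.ndarray:
    """The package's default working grid: 300-700 nm at 1-nm steps."""
    return np.arange(start, stop + step / 2, step, dtype=float)


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral curve: per-wavelength values on a strictly increasing grid.

    Parameters
    ----------
    wavelengths
        Sample positions in nm, strictly increasing.
    values
        One value per wavelength. Reflectance is a fraction (0-1 under
        normal measurement; negative instrument artefacts are permitted
        until :func:`clamp_nonnegative`), illuminants are relative photon
        flux or spectral power, sensitivities are relative (typically
        unit-peak).
    kind
        One of ``reflectance``, ``illuminant``, ``sensitivity``.
    name
        Optional label carried through tables and plots.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise SpectrumFormatError(
                f"wavelengths and values must be 1-D and equal length "
                f"(got {wl.shape} and {vals.shape})"
            )
        if wl.size < 2:
            raise SpectrumFormatError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumFormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise SpectrumFormatError(f"non-finite values in spectrum {self.name!r}")
        if self.kind not in KINDS:
            raise SpectrumFormatError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    def same_grid(self, other: "Spectrum") -> bool:
        return self.wavelengths.size == other.wavelengths.size and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated value at one wavelength (no extrapolation)."""
        wl = float(wavelength)
        if wl < self.wavelengths[0] or wl > self.wavelengths[-1]:
            raise SpectrumRangeError(
                f"{wl} nm outside measured range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        return float(np.interp(wl, self.wavelengths, self.values))


def resample(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    The grid must lie within the measured wavelength range; values at
    original sample positions are preserved exactly. Extrapolation is
    refused (:class:`SpectrumRangeError`) — silently extending measured
    spectra is the classic spectral-processing bug.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 2 or not np.all(np.diff(g) > 0):
        raise SpectrumFormatError("grid must be 1-D and strictly increasing")
    if g[0] < s.wavelengths[0] or g[-1] > s.wavelengths[-1]:
        raise SpectrumRangeError(
            f"grid [{g[0]}, {g[-1]}] nm exceeds measured range "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}] nm; extrapolation refused"
        )
    vals = np.interp(g, s.wavelengths, s.values)
    return replace(s, wavelengths=g, values=vals)


def clamp_nonnegative(s: Spectrum) -> tuple[Spectrum, int]:
    """Convert negative values (instrument noise artefacts) to zero.

    Returns the clamped spectrum and the number of samples that were
    negative, so pipelines can report how much was altered.
    """
    negative = s.values < 0
    n_clamped = int(np.count_nonzero(negative))
    if n_clamped == 0:
        return s, 0
    return replace(s, values=np.where(negative, 0.0, s.values)), n_clamped


@dataclass
class SpectralLibrary:
    """A named, ordered collection of spectra sharing one wavelength grid.

    Use :meth:`harmonize` to resample every member onto a common grid;
    most downstream operations require this.
    """

    spectra: dict[str, Spectrum] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra.values())

    def __getitem__(self, name: str) -> Spectrum:
        return self.spectra[name]

    def __contains__(self, name: str) -> bool:
        return name in self.spectra

    @property
    def names(self) -> list[str]:
        return list(self.spectra)

    def add(self, s: Spectrum) -> None:
        if not s.name:
            raise SpectrumFormatError("library members need a name")
        self.spectra[s.name] = s

    def harmonize(self, grid: Sequence[float] | None = None) -> "SpectralLibrary":
        """Resample every member onto ``grid`` (default: the first member's grid)."""
        if not self.spectra:
            return SpectralLibrary()
        g = np.asarray(
            grid if grid is not None else next(iter(self.spectra.values())).wavelengths,
            dtype=float,
        )
        return SpectralLibrary({name: resample(s, g) for name, s in self.spectra.items()})

    @property
    def common_grid(self) -> np.ndarray:
        """The shared grid; raises if members disagree."""
        members = list(self.spectra.values())
        if not members:
            raise SpectrumFormatError("empty library has no grid")
        first = members[0]
        for s in members[1:]:
            if not first.same_grid(s):
                raise SpectrumFormatError(
                    f"library not harmonized: {s.name!r} is on a different grid"
                )
        return first.wavelengths

    def to_frame(self) -> pd.DataFrame:
        """Wide table: wavelength_nm column plus one column per spectrum."""
        grid = self.common_grid
        data = {"wavelength_nm": grid}
        for name, s in self.spectra.items():
            data[name] = s.values
        return pd.DataFrame(data)


def read_spectrum_table(
    path: str | Path,
    value_scale: str = "fraction",
    kind: str = "reflectance",
) -> SpectralLibrary:
    """Read a CSV spectral table into a :class:`SpectralLibrary`.

    Expected dialect: a header row, first column ``wavelength_nm`` (any
    name is accepted positionally), then one column per spectrum. With
    ``value_scale="percent"`` values are divided by 100 on read; the
    internal unit is always the fraction.
    """
    if value_scale not in ("fraction", "percent"):
        raise SpectrumFormatError(f"value_scale must be fraction|percent, got {value_scale!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, header=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpectrumFormatError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: need a wavelength column plus >=1 value column")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise SpectrumFormatError(
            f"{path}: non-numeric cell at data row {row + 1}, column {frame.columns[col]!r}"
        )
    wl = numeric.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise SpectrumFormatError(f"{path}: wavelengths must be strictly increasing")
    scale = 0.01 if value_scale == "percent" else 1.0
    lib = SpectralLibrary()
    for col in frame.columns[1:]:
        lib.add(
            Spectrum(
                wavelengths=wl,
                values=numeric[col].to_numpy(dtype=float) * scale,
                kind=kind,
                name=str(col),
            )
        )
    return lib


# ---------------------------------------------------------------------------
# synthetic reflectance generators


def flat_reflectance(level: float, grid: Sequence[float] | None = None, name: str = "") -> Spectrum:
    """Spectrally flat (achromatic) reflectance at ``level`` (fraction, 0-1)."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"reflectance level must be in [0, 1], got {level}")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(g, np.full(g.size, float(level)), kind="reflectance",
                    name=name or f"flat_{level:g}")


def logistic_reflectance(
    midpoint: float,
    lower: float = 0.10,
    upper: float = 0.60,
    slope: float = 0.05,
    grid: Sequence[float] | None = None,
    name: str = "",
) -> Spectrum:
    """Sigmoid reflectance rising from ``lower`` to ``upper`` around ``midpoint``.

    value(λ) = lower + (upper − lower) / (1 + exp(−slope·(λ − midpoint)))

    These step-like spectra mimic the long-pass reflectance of many
    natural pigments; sweeping the midpoint across the visible range
    produces a hue series. Defaults give 10-60% reflectance with a
    transition roughly 100 nm wide.
    """
    if lower >= upper:
        raise ValueError(f"need lower < upper, got {lower} >= {upper}")
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    vals = lower + (upper - lower) / (1.0 + np.exp(-slope * (g - midpoint)))
    return Spectrum(g, vals, kind="reflectance", name=name or f"logistic_{midpoint:g}")


def gaussian_reflectance(
    center: float,
    sd: float,
    peak: float,
    baseline: float = 0.0,
    grid: Sequence[float] | None = None,
    name: str = "",
) -> Spectrum:
    """Band reflectance: Gaussian bump of height ``peak`` over ``baseline``."""
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    if not 0.0 <= baseline < peak <= 1.0:
        raise ValueError(f"need 0 <= baseline < peak <= 1, got {baseline}, {peak}")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    vals = baseline + (peak - baseline) * np.exp(-((g - center) ** 2) / (2.0 * sd**2))
    return Spectrum(g, vals, kind="reflectance", name=name or f"gaussian_{center:g}")


def shift_reflectance(s: Spectrum, delta: float) -> Spectrum:
    """Shift reflectance by ``delta`` percentage points, clamped at zero.

    ``delta = -10`` removes ten percentage points everywhere, the
    standard way to emulate a stimulus darker than its measurement
    suggests (spectrometric offset error).
    """
    vals = np.maximum(s.values + delta / 100.0, 0.0)
    return replace(s, values=vals, name=f"{s.name}{delta:+g}pp" if s.name else "")


# ---------------------------------------------------------------------------
# sensitivity curves


def gaussian_sensitivity(
    lambda_max: float,
    sd: float = 50.0,
    grid: Sequence[float] | None = None,
    name: str = "",
) -> Spectrum:
    """Unit-peak Gaussian photoreceptor sensitivity centred at ``lambda_max``."""
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    vals = np.exp(-((g - lambda_max) ** 2) / (2.0 * sd**2))
    return Spectrum(g, vals, kind="sensitivity", name=name or f"sens_{lambda_max:g}")


def pigment_template(
    lambda_max: float,
    grid: Sequence[float] | None = None,
    beta_band: bool = True,
    name: str = "",
) -> Spectrum:
    """A1 visual-pigment absorbance template (Govardovskii et al. 2000 nomogram).

    A more physiological alternative to :func:`gaussian_sensitivity`:
    an asymmetric alpha band peaking at ``lambda_max`` plus an optional
    UV beta band. Used for the packaged honeybee-like receptor set.
    """
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    x = lambda_max / g
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    vals = alpha
    if beta_band:
        lam_beta = 189.0 + 0.315 * lambda_max
        bandwidth = -40.5 + 0.195 * lambda_max
        beta = 0.26 * np.exp(-(((g - lam_beta) / bandwidth) ** 2))
        vals = alpha + beta
    vals = vals / vals.max()
    return Spectrum(g, vals, kind="sensitivity", name=name or f"pigment_{lambda_max:g}")


# ---------------------------------------------------------------------------
# illuminants and backgrounds

# CIE standard illuminant D65, relative spectral power at 10-nm resolution,
# 300-700 nm (100 at 560 nm by convention).
_D65_WL = np.arange(300.0, 701.0, 10.0)
_D65_POWER = np.array([
    0.034, 3.294, 20.236, 37.054, 39.950, 44.911, 46.638, 52.089, 49.975,
    54.648, 82.755, 91.486, 93.432, 86.682, 104.865, 117.008, 117.812,
    114.861, 115.923, 108.811, 109.354, 107.802, 104.790, 107.689, 104.405,
    104.046, 100.000, 96.334, 95.788, 88.686, 90.006, 89.599, 87.699,
    83.289, 83.700, 80.027, 80.215, 82.278, 78.284, 69.721, 71.609,
])


def builtin_illuminant(name: str, grid: Sequence[float] | None = None) -> Spectrum:
    """A packaged illuminant: ``"D65"`` (midday open-air daylight) or ``"flat"``.

    D65 is the CIE reference daylight tabulated at 10-nm resolution and
    linearly interpolated to the working grid; ``flat`` is constant
    photon flux, useful for controlled synthetic experiments.
    """
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    key = name.strip().lower()
    if key == "d65":
        base = Spectrum(_D65_WL, _D65_POWER, kind="illuminant", name="D65")
        return resample(base, g)
    if key == "flat":
        return Spectrum(g, np.ones(g.size), kind="illuminant", name="flat")
    raise KeyError(f"unknown illuminant {name!r}; available: D65, flat")


def leaf_background(grid: Sequence[float] | None = None) -> Spectrum:
    """Synthetic chromatic (leaf-like) background reflectance.

    Synthetic stand-in for an averaged green-vegetation background: low
    UV reflectance, a green peak near 550 nm, and a red-edge rise toward
    700 nm. Any measured background CSV can be used in its place.
    """
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    green = 0.12 * np.exp(-((g - 550.0) ** 2) / (2.0 * 40.0**2))
    red_edge = 0.25 / (1.0 + np.exp(-0.08 * (g - 705.0)))
    vals = 0.02 + green + red_edge
    return Spectrum(g, vals, kind="reflectance", name="leaf_background")


def synthetic_flora(
    n: int,
    grid: Sequence[float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> SpectralLibrary:
    """Generate ``n`` random flower-like reflectance spectra.

    Each spectrum is a baseline plus one or two Gaussian bands and an
    optional long-pass shoulder — broadly the shapes found in flower
    reflectance databases. Deterministic for a fixed seed.
    """
    g = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lib = SpectralLibrary()
    for k in range(n):
        baseline = rng.uniform(0.01, 0.10)
        vals = np.full(g.size, baseline)
        for _ in range(rng.integers(1, 3)):
            center = rng.uniform(320.0, 680.0)
            sd = rng.uniform(25.0, 90.0)
            height = rng.uniform(0.1, 0.7)
            vals = vals + height * np.exp(-((g - center) ** 2) / (2.0 * sd**2))
        if rng.random() < 0.4:  # long-pass shoulder (red/white flowers)
            mid = rng.uniform(500.0, 650.0)
            vals = vals + rng.uniform(0.1, 0.5) / (1.0 + np.exp(-0.05 * (g - mid)))
        np.clip(vals, 0.0, 1.0, out=vals)
        lib.add(Spectrum(g, vals, kind="reflectance", name=f"flower_{k:03d}"))
    return lib
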