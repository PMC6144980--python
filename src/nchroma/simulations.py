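"""Simulation harnesses: stimulus sweeps, model concordance, receptor screening.

Four study designs for probing model behaviour:

* :func:`midpoint_sweep` — a hue series of logistic (step-like)
  reflectances with midpoints swept across the spectrum, optionally
  shifted down by a fixed number of percentage points to push stimulus
  catches below the background catch (the regime where log-transforming,
  output-normalizing models produce spurious distances).
* :func:`achromatic_sweep` — spectrally flat stimuli of increasing
  reflectance viewed against a chromatic (e.g. leaf-like) background,
  separating models that are intensity-invariant from those that are not.
* :func:`compare_models` — pairwise Spearman rank concordance between
  the ΔS series different models assign to one stimulus set.
* :func:`screen_receptor_sets` — exhaustive evaluation of candidate
  photoreceptor peak-wavelength combinations against a stimulus library,
  ranked by mean ΔS (a simple proxy for discrimination performance).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ModelConfigError
from .geometry import chromaticity_basis
from .models import ModelConfig, ModelResult, run_model
from .photon_catch import PhotoreceptorSet, em_relative, transform_output
from .spectra import (
    SpectralLibrary,
    Spectrum,
    flat_reflectance,
    logistic_reflectance,
    shift_reflectance,
)

__all__ = [
    "SweepResult",
    "ScreeningResult",
    "midpoint_sweep",
    "achromatic_sweep",
    "screen_receptor_sets",
    "compare_models",
]


@dataclass(frozen=True)
class SweepResult:
    """One row per stimulus of a parameter sweep, plus the per-stimulus results.

    ``table`` columns: the sweep parameter, per-receptor outputs
    E_1..E_i, locus coordinates X_1..X_n, ``delta_s``, and a ``spurious``
    flag set whenever the model emitted a warning for that stimulus.
    """

    parameter: str
    table: pd.DataFrame
    results: tuple[ModelResult, ...]

    @property
    def peak(self) -> tuple[float, float]:
        """(parameter value, ΔS) at the maximum ΔS."""
        idx = int(self.table["delta_s"].idxmax())
        row = self.table.loc[idx]
        return float(row[self.parameter]), float(row["delta_s"])

    @property
    def n_spurious(self) -> int:
        return int(self.table["spurious"].sum())


def _sweep_table(parameter: str, values: Sequence[float],
                 results: Sequence[ModelResult]) -> pd.DataFrame:
    rows = []
    for value, res in zip(values, results):
        row: dict[str, object] = {parameter: value}
        for j, e in enumerate(res.catch.E, start=1):
            row[f"E_{j}"] = e
        for j, x in enumerate(res.locus, start=1):
            row[f"X_{j}"] = x
        row["delta_s"] = res.delta_s_background
        row["spurious"] = bool(res.warnings)
        row["warnings"] = "; ".join(res.warnings)
        rows.append(row)
    return pd.DataFrame(rows)


def midpoint_sweep(
    receptors: PhotoreceptorSet,
    illuminant: Spectrum,
    background: Spectrum,
    config: ModelConfig,
    midpoints: Sequence[float] | None = None,
    lower: float = 0.10,
    upper: float = 0.60,
    slope: float = 0.05,
    shift: float = 0.0,
) -> SweepResult:
    """Run a model over logistic reflectances with swept midpoints.

    Defaults follow the standard design: midpoints 300-700 nm at 5-nm
    steps (81 spectra) spanning 10-60% reflectance. ``shift`` (in
    percentage points, e.g. -10) displaces every stimulus after
    generation, clamped at zero — the construction that drives stimulus
    catches below an achromatic background's.
    """
    grid = receptors.grid
    if midpoints is None:
        midpoints = np.arange(300.0, 701.0, 5.0)
    midpoints = np.asarray(midpoints, dtype=float)
    results = []
    for mp in midpoints:
        stim = logistic_reflectance(mp, lower=lower, upper=upper, slope=slope, grid=grid)
        if shift:
            stim = shift_reflectance(stim, shift)
        results.append(run_model(stim, background, illuminant, receptors, config))
    return SweepResult(
        parameter="midpoint_nm",
        table=_sweep_table("midpoint_nm", midpoints, results),
        results=tuple(results),
    )


def achromatic_sweep(
    receptors: PhotoreceptorSet,
    illuminant: Spectrum,
    background: Spectrum,
    config: ModelConfig,
    levels: Sequence[float] | None = None,
) -> SweepResult:
    """Run a model over flat achromatic stimuli of increasing reflectance.

    Default levels are 5% to 95% in 10-point steps. Against a chromatic
    background the log-RNL model assigns every level the same ΔS (ln
    differences are intensity-invariant), the linear RNL model's ΔS
    grows linearly with level, and the bounded-transform models assign
    the *darkest* stimuli the largest distances.
    """
    grid = receptors.grid
    if levels is None:
        levels = np.arange(0.05, 0.96, 0.10)
    levels = np.asarray(levels, dtype=float)
    results = [
        run_model(flat_reflectance(lv, grid=grid), background, illuminant, receptors, config)
        for lv in levels
    ]
    return SweepResult(
        parameter="reflectance_level",
        table=_sweep_table("reflectance_level", levels, results),
        results=tuple(results),
    )


# ---------------------------------------------------------------------------
# model concordance


def compare_models(delta_s_tables: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between models' ΔS series.

    Input maps model names to equal-length ΔS lists over one common,
    identically ordered stimulus set. Returns a long-format table with
    columns ``model_a``, ``model_b``, ``rho``, ``p_value``, ``n``
    (two-sided p, average ranks for ties).
    """
    names = list(delta_s_tables)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    arrays = {name: np.asarray(delta_s_tables[name], dtype=float) for name in names}
    n = arrays[names[0]].size
    for name, arr in arrays.items():
        if arr.ndim != 1 or arr.size != n:
            raise ValueError(
                f"ΔS series {name!r} has length {arr.size}, expected {n}: "
                "series must be paired over one stimulus set"
            )
    rows = []
    for a, b in itertools.combinations(names, 2):
        rho, p = stats.spearmanr(arrays[a], arrays[b])
        rows.append({"model_a": a, "model_b": b, "rho": float(rho),
                     "p_value": float(p), "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# receptor-set screening


@dataclass(frozen=True)
class ScreeningResult:
    """Ranked evaluation of photoreceptor peak combinations.

    ``table`` columns: ``n_receptors``, ``peaks_nm`` (sorted tuple),
    ``mean_delta_s``, ``rank`` (1 = best overall). Ties rank in
    lexicographic peak order, so the ranking is deterministic.
    """

    table: pd.DataFrame
    n_stimuli: int

    @property
    def n_combinations(self) -> int:
        return len(self.table)

    def best(self, n_receptors: int | None = None) -> tuple[float, ...]:
        """Peak set with the highest mean ΔS (optionally within one set size)."""
        t = self.table
        if n_receptors is not None:
            t = t[t["n_receptors"] == n_receptors]
            if t.empty:
                raise ValueError(f"no combinations of size {n_receptors}")
        return tuple(t.loc[t["rank"].idxmin(), "peaks_nm"])


def _delta_s_batch(
    E: np.ndarray, config: ModelConfig, basis, whitener: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """ΔS to background for a batch of output vectors (rows of E).

    Mirrors the per-stimulus pipeline of :func:`~nchroma.models.run_model`
    in vectorized form; agreement is asserted by the test suite.
    """
    i = E.shape[1]
    spurious = np.zeros(E.shape[0], dtype=bool)
    if config.use_noise:
        E_bg = transform_output(np.ones(i), config.transform, config.custom_transform)
        x = (E - E_bg) @ basis.V.T
        s = x @ whitener.T
        return np.linalg.norm(s, axis=1), spurious
    if config.relative_outputs:
        p = np.empty_like(E)
        for r in range(E.shape[0]):
            if np.ptp(E[r]) == 0.0:
                p[r] = 1.0 / i
            else:
                import warnings as _warnings

                with _warnings.catch_warnings(record=True) as caught:
                    _warnings.simplefilter("always")
                    p[r] = em_relative(E[r])
                spurious[r] = bool(caught)
        E = p
    x = E @ basis.V.T
    return np.linalg.norm(x, axis=1), spurious


def screen_receptor_sets(
    stimuli: SpectralLibrary,
    background: Spectrum,
    illuminant: Spectrum,
    candidate_peaks: Sequence[float],
    set_sizes: Sequence[int],
    config: ModelConfig,
    sensitivity_sd: float = 50.0,
    n_stimuli: int | None = None,
    seed: int | None = None,
) -> ScreeningResult:
    """Exhaustively rank photoreceptor peak-wavelength combinations.

    For every combination of ``candidate_peaks`` of each size in
    ``set_sizes``, builds Gaussian sensitivity curves, runs every
    stimulus through the configured model against ``background``, and
    records the mean ΔS. The selection rule is the maximum mean ΔS;
    ties break lexicographically by peak wavelengths. ``n_stimuli``
    subsamples the library reproducibly under ``seed``.
    """
    peaks = sorted(float(p) for p in candidate_peaks)
    if len(set(peaks)) != len(peaks):
        raise ValueError("candidate peaks must be distinct")
    for k in set_sizes:
        if k < 2:
            raise ValueError(f"set sizes must be >= 2, got {k}")
        if k > len(peaks):
            raise ValueError(f"set size {k} exceeds {len(peaks)} candidate peaks")

    grid = background.wavelengths
    names = stimuli.names
    if n_stimuli is not None and n_stimuli < len(names):
        rng = np.random.default_rng(seed)
        names = sorted(rng.choice(names, size=n_stimuli, replace=False))
    chosen = [stimuli[name] for name in names]
    for s in chosen + [illuminant]:
        if not background.same_grid(s):
            raise ModelConfigError(
                "stimuli, background and illuminant must share one grid; "
                "harmonize the library first"
            )

    # trapezoid quadrature weights make Q computation a matrix product
    w = np.gradient(grid)
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    stim_flux = np.array([s.values * illuminant.values * w for s in chosen])
    bg_flux = background.values * illuminant.values * w

    sens_cache = {
        p: np.exp(-((grid - p) ** 2) / (2.0 * sensitivity_sd**2)) for p in peaks
    }

    rows = []
    for k in sorted(set_sizes):
        basis = chromaticity_basis(k, config.scale_mode, config.scale_value)
        for combo in itertools.combinations(peaks, k):
            S = np.array([sens_cache[p] for p in combo])  # k x grid
            Q = stim_flux @ S.T  # n_stim x k
            Q_bg = bg_flux @ S.T
            q = Q / Q_bg
            E = np.array([
                transform_output(q_row, config.transform, config.custom_transform)
                for q_row in q
            ])
            whitener = None
            if config.use_noise:
                noise = np.asarray(config.resolved_noise(k), dtype=float)
                from .models import _spd_inverse_sqrt

                whitener = _spd_inverse_sqrt(basis.V @ np.diag(noise**2) @ basis.V.T)
            delta_s, spurious = _delta_s_batch(E, config, basis, whitener)
            rows.append({
                "n_receptors": k,
                "peaks_nm": tuple(combo),
                "mean_delta_s": float(delta_s.mean()),
                "n_spurious": int(spurious.sum()),
            })
    table = pd.DataFrame(rows)
    # deterministic ranking: mean ΔS descending, lexicographic peaks on ties
    order = table.sort_values(
        by=["mean_delta_s", "peaks_nm"], ascending=[False, True], kind="mergesort"
    ).index
    table["rank"] = 0
    table.loc[order, "rank"] = np.arange(1, len(table) + 1)
    return ScreeningResult(table=table, n_stimuli=len(chosen))
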