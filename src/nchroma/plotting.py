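"""Minimal 2-D chromaticity-diagram plotting (trichromat spaces, n = 2)."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .geometry import ChromaticityBasis

__all__ = ["plot_chromaticity"]


def plot_chromaticity(
    basis: ChromaticityBasis,
    loci: Mapping[str, Sequence[float]],
    boundary: str | None = None,
    path: str | None = None,
    ax=None,
):
    """Scatter color loci in a 2-D chromaticity diagram.

    ``boundary="hexagon"`` draws the hexagonal gamut of bounded
    hyperbolic outputs (vertices at ± the receptor vectors);
    ``boundary="simplex"`` draws the triangle of sum-to-1 relative
    outputs (vertices at the receptor vectors). RNL spaces have no
    boundary. Only n = 2 (trichromat) spaces are drawn; higher
    dimensions are out of scope for plotting.
    """
    if basis.n != 2:
        raise ValueError(f"only 2-D chromaticity diagrams are drawn (basis n={basis.n})")
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if boundary == "hexagon":
        verts = np.hstack([basis.V, -basis.V]).T
    elif boundary == "simplex":
        verts = basis.V.T
    elif boundary is None:
        verts = None
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    if verts is not None:
        order = np.argsort(np.arctan2(verts[:, 1], verts[:, 0]))
        poly = np.vstack([verts[order], verts[order][:1]])
        ax.plot(poly[:, 0], poly[:, 1], color="0.4", lw=1)
    ax.axhline(0, color="0.85", lw=0.5, zorder=0)
    ax.axvline(0, color="0.85", lw=0.5, zorder=0)
    xs = np.array([np.asarray(v, dtype=float) for v in loci.values()])
    if xs.size:
        ax.scatter(xs[:, 0], xs[:, 1], s=14, c=np.arange(len(xs)), cmap="viridis")
    ax.plot(0, 0, "k+", ms=8)
    ax.set_xlabel("$X_1$")
    ax.set_ylabel("$X_2$")
    ax.set_aspect("equal")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
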