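"""Chromaticity-space geometry: equidistant receptor vectors and color loci.

An animal with i photoreceptor types whose outputs are all opposed
against each other has a chromaticity diagram of n = i - 1 dimensions:
each receptor contributes one vector, all vectors have equal length,
every pair subtends the same angle arccos(-1/n), and the vectors sum to
zero (so equal outputs — the adapted background — land on the origin).
The i vectors are the columns of the basis matrix V; a stimulus with
output vector p has color locus x = V·p, and chromatic distance between
stimuli is the Euclidean distance between loci.

This construction contains the classic spaces as special cases: the
dichromat segment, the trichromat hexagon/triangle (120° vectors), the
tetrachromat tetrahedron (109.47°), and any higher dimensionality.
Orientation of V carries no biological meaning; the construction here is
deterministic, and any rigid rotation leaves all distances unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "pairwise_angle",
    "generic_unit_vector",
    "ChromaticityBasis",
    "chromaticity_basis",
    "unit_vertex_distance",
    "color_locus",
    "euclidean_delta_s",
]

_BASIS_TOL = 1e-10


def pairwise_angle(n: int) -> float:
    """Common angle (radians) between receptor vectors in n dimensions.

    θ = arccos(−1/n): π for a dichromat's 1-D diagram, 120° for a
    trichromat, 109.47° for a tetrachromat — the unique angle at which
    n + 1 equal-length vectors can sum to zero.
    """
    if n < 1:
        raise ValueError(f"dimensionality must be >= 1, got {n}")
    return float(np.arccos(-1.0 / n))


def generic_unit_vector(n: int) -> np.ndarray:
    """The generator vector of the equidistant construction (unit length).

    Built back to front: the last component is cos θ = −1/n, and each
    earlier component v[n−k] = −(1/(n−k))·sqrt(1 − Σ_{m>n−k} v_m²)
    absorbs the remaining length. Every basis column is this vector with
    sign/multiplicity bookkeeping applied.
    """
    if n < 1:
        raise ValueError(f"dimensionality must be >= 1, got {n}")
    v = np.zeros(n)
    v[n - 1] = -1.0 / n  # cos(theta)
    for k in range(1, n):
        idx = n - k - 1  # zero-based position of component n-k
        tail = v[idx + 1:]
        v[idx] = -(1.0 / (n - k)) * np.sqrt(1.0 - float(tail @ tail))
    return v


def unit_vertex_distance(i: int) -> float:
    """Tip-to-tip distance between unit receptor vectors: sqrt(2i/(i−1))."""
    if i < 2:
        raise ValueError(f"need at least two receptors, got {i}")
    return float(np.sqrt(2.0 * i / (i - 1.0)))


@dataclass(frozen=True)
class ChromaticityBasis:
    """The matrix V of i equidistant vectors spanning an (i−1)-D color space.

    Columns of ``V`` (shape n × i) are the receptor vectors. All columns
    share one length (``column_length``), every pair of distinct columns
    has dot product −length²/n, and the columns sum to the zero vector.
    ``scale_mode`` records whether the space was sized by receptor-vector
    length or by the distance between adjacent diagram vertices.
    """

    V: np.ndarray
    i: int
    n: int
    theta: float
    scale_mode: str
    scale_value: float
    column_length: float

    @property
    def vertex_distance(self) -> float:
        """Distance between the tips of any two receptor vectors."""
        return self.column_length * unit_vertex_distance(self.i)

    @property
    def unit_V(self) -> np.ndarray:
        """The basis rescaled to unit columns."""
        return self.V / self.column_length


def _simplex_matrix(i: int) -> np.ndarray:
    """Unit-column V for i receptors: row k is (v_k ×k, −k·v_k, 0…)."""
    n = i - 1
    v = generic_unit_vector(n)
    V = np.zeros((n, i))
    for k in range(1, n + 1):
        V[k - 1, :k] = v[k - 1]
        V[k - 1, k] = -k * v[k - 1]
    return V


def _check_invariants(V: np.ndarray, n: int, length: float) -> None:
    gram = V.T @ V
    lengths = np.sqrt(np.diag(gram))
    if not np.allclose(lengths, length, atol=_BASIS_TOL, rtol=0):
        raise RuntimeError("basis columns do not share the configured length")
    off = gram[~np.eye(gram.shape[0], dtype=bool)]
    if not np.allclose(off, -(length**2) / n, atol=_BASIS_TOL, rtol=0):
        raise RuntimeError("basis columns are not equiangular at arccos(-1/n)")
    if not np.allclose(V.sum(axis=1), 0.0, atol=_BASIS_TOL, rtol=0):
        raise RuntimeError("basis columns do not sum to zero")


def chromaticity_basis(
    i: int,
    scale_mode: str = "vector_length",
    scale_value: float = 1.0,
) -> ChromaticityBasis:
    """Construct the chromaticity basis for ``i`` photoreceptor types.

    ``scale_mode="vector_length"`` fixes every receptor vector's length
    to ``scale_value`` (1 for the hexagon-style models, 0.75 for the
    Endler–Mielke convention). ``scale_mode="vertex_distance"`` instead
    fixes the distance between adjacent diagram vertices, the natural
    convention when comparing spaces of different dimensionality: for
    unit columns that distance is sqrt(2i/(i−1)), so columns are rescaled
    by scale_value / sqrt(2i/(i−1)).

    The three defining invariants (equal column length, pairwise dot
    product −length²/n, zero column sum) are verified on every call.
    """
    if i < 2:
        raise ValueError(f"need at least two receptors, got {i}")
    if scale_value <= 0:
        raise ValueError(f"scale_value must be positive, got {scale_value}")
    n = i - 1
    V = _simplex_matrix(i)
    if scale_mode == "vector_length":
        length = float(scale_value)
    elif scale_mode == "vertex_distance":
        length = float(scale_value) / unit_vertex_distance(i)
    else:
        raise ValueError(
            f"scale_mode must be vector_length|vertex_distance, got {scale_mode!r}"
        )
    V = V * length
    _check_invariants(V, n, length)
    return ChromaticityBasis(
        V=V,
        i=i,
        n=n,
        theta=pairwise_angle(n),
        scale_mode=scale_mode,
        scale_value=float(scale_value),
        column_length=length,
    )


def color_locus(basis: ChromaticityBasis, p: Sequence[float]) -> np.ndarray:
    """Color locus x = V·p of a stimulus with photoreceptor outputs ``p``.

    Because the columns of V sum to zero, adding the same constant to
    every output leaves the locus unchanged: only differences between
    photoreceptor outputs carry chromatic information.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (basis.i,):
        raise ValueError(
            f"output vector has shape {p.shape}; basis expects ({basis.i},)"
        )
    if not np.all(np.isfinite(p)):
        raise ValueError("photoreceptor outputs must be finite")
    return basis.V @ p


def euclidean_delta_s(a: Sequence[float], b: Sequence[float] | None = None) -> float:
    """Chromatic distance ΔS: Euclidean distance between two color loci.

    With ``b`` omitted, distance to the origin (the adapted background).
    """
    a = np.asarray(a, dtype=float)
    b = np.zeros_like(a) if b is None else np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"loci have different dimensions: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
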