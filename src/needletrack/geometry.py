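"""Sparse Fermat's-spiral transducer layouts and inner-to-outer sparsification.

A 2D matrix-array probe fires single elements sequentially during the tracking
phase, so the tracking frame rate is set directly by how many elements are
active.  Elements are laid out on a Fermat spiral (radius ∝ √k with
golden-angle azimuthal steps), a low-redundancy sampling of the aperture, and
sparsified from the innermost elements outward: the outermost ring is kept
because it preserves the full aperture and hence angular diversity for
range-based localization.

Units are millimetres throughout; elements lie in the z = 0 plane with +z
pointing into the medium.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    GeometryError,
    InfeasibleGeometryError,
    InvalidPlanError,
    InvalidSubsetError,
)

#: Golden angle in radians, the azimuthal increment of the Fermat spiral.
GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

MIN_ELEMENTS = 3


@dataclass(frozen=True)
class ElementLayout:
    """Identities and 3D coordinates of the active transducer elements.

    Parameters
    ----------
    element_ids : (N,) int array
        Stable element identifiers.
    positions : (N, 3) float array
        Element centres in mm, probe coordinate frame; all z exactly 0.
    radial_rank : (N,) int array
        Permutation of 0..N-1; 0 is the innermost element by distance from
        the layout centroid.
    """

    element_ids: np.ndarray
    positions: np.ndarray
    radial_rank: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = np.asarray(self.element_ids, dtype=int)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError("positions must be an (N, 3) array")
        if ids.shape != (pos.shape[0],):
            raise GeometryError("element_ids must align with positions")
        if pos.shape[0] < MIN_ELEMENTS:
            raise GeometryError(
                f"at least {MIN_ELEMENTS} elements required, got {pos.shape[0]}"
            )
        if np.any(pos[:, 2] != 0.0):
            raise GeometryError("all element z-coordinates must be exactly 0")
        if len(np.unique(ids)) != len(ids):
            raise GeometryError("element_ids must be unique")
        # pairwise-distinct positions
        order = np.lexsort(pos.T)
        if np.any(np.all(np.diff(pos[order], axis=0) == 0.0, axis=1)):
            raise GeometryError("element positions must be pairwise distinct")
        rank = self.radial_rank
        if rank is None:
            rank = _radial_rank(pos)
        rank = np.asarray(rank, dtype=int)
        if sorted(rank) != list(range(len(ids))):
            raise GeometryError("radial_rank must be a permutation of 0..N-1")
        object.__setattr__(self, "element_ids", ids)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "radial_rank", rank)

    @property
    def n_elements(self) -> int:
        return len(self.element_ids)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def radii(self) -> np.ndarray:
        """Distance of each element from the layout centroid (mm)."""
        return np.linalg.norm(self.positions - self.centroid, axis=1)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "element_id": self.element_ids,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ElementLayout":
        df = pd.read_csv(path)
        return cls._from_table(df)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "element_id": self.element_ids.tolist(),
                    "x_mm": self.positions[:, 0].tolist(),
                    "y_mm": self.positions[:, 1].tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ElementLayout":
        with open(path) as fh:
            return cls._from_table(pd.DataFrame(json.load(fh)))

    @classmethod
    def from_file(cls, path) -> "ElementLayout":
        path = str(path)
        return cls.from_json(path) if path.endswith(".json") else cls.from_csv(path)

    @classmethod
    def _from_table(cls, df: pd.DataFrame) -> "ElementLayout":
        required = {"element_id", "x_mm", "y_mm"}
        if not required.issubset(df.columns):
            raise GeometryError(f"geometry table needs columns {sorted(required)}")
        pos = np.column_stack(
            [df["x_mm"].to_numpy(float), df["y_mm"].to_numpy(float), np.zeros(len(df))]
        )
        return cls(df["element_id"].to_numpy(int), pos)


@dataclass(frozen=True)
class SparsificationPlan:
    """Nested inner-to-outer element subsets, largest first."""

    subset_sizes: tuple
    subsets: dict  # size -> (k,) array of element_ids

    def subset_ids(self, size: int) -> np.ndarray:
        return self.subsets[size]


def _radial_rank(positions: np.ndarray) -> np.ndarray:
    """Rank elements by non-decreasing distance from the centroid.

    Stable sort so equidistant elements are ordered by index, making the
    sparsification deterministic for any geometry.
    """
    radii = np.linalg.norm(positions - positions.mean(axis=0), axis=1)
    order = np.argsort(radii, kind="stable")
    rank = np.empty(len(radii), dtype=int)
    rank[order] = np.arange(len(radii))
    return rank


def generate_fermat_spiral(
    n_elements: int, scale: float, pitch: float | None = None
) -> ElementLayout:
    """Generate an N-element Fermat-spiral layout, optionally grid-snapped.

    Positions follow r_k = scale·√k, θ_k = k·golden angle.  When ``pitch`` is
    given, each position is snapped to the nearest node of a rectangular grid
    of that pitch (emulating a physical matrix array whose elements sit on a
    fixed lattice); a collision with an already-occupied node is resolved by
    moving to the nearest free node, never farther than one grid diagonal.

    Parameters
    ----------
    n_elements : int
        Number of elements (≥ 3).
    scale : float
        Spiral scale in mm; the outermost radius is scale·√(N−1).
    pitch : float, optional
        Rectangular grid pitch in mm for snapping; ``None`` disables snapping.
    """
    if n_elements < MIN_ELEMENTS:
        raise GeometryError(f"n_elements must be ≥ {MIN_ELEMENTS}, got {n_elements}")
    if scale <= 0:
        raise GeometryError(f"scale must be positive, got {scale}")
    if pitch is not None and pitch <= 0:
        raise GeometryError(f"pitch must be positive, got {pitch}")

    k = np.arange(n_elements)
    r = scale * np.sqrt(k)
    theta = k * GOLDEN_ANGLE
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros(n_elements)])

    if pitch is not None:
        pos = _snap_to_grid(pos, pitch)

    return ElementLayout(element_ids=k, positions=pos, radial_rank=_radial_rank(pos))


def _snap_to_grid(pos: np.ndarray, pitch: float) -> np.ndarray:
    """Snap positions to grid nodes, resolving collisions to the nearest free node."""
    max_disp = pitch * math.sqrt(2.0)  # one grid diagonal
    occupied: set = set()
    out = np.zeros_like(pos)
    # candidate node offsets within one diagonal of the nearest node, sorted by
    # distance so the first free candidate is the nearest one
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    for idx in range(len(pos)):
        x, y = pos[idx, 0], pos[idx, 1]
        i0, j0 = round(x / pitch), round(y / pitch)
        candidates = sorted(
            ((i0 + di, j0 + dj) for di, dj in offsets),
            key=lambda ij: (ij[0] * pitch - x) ** 2 + (ij[1] * pitch - y) ** 2,
        )
        placed = False
        for i, j in candidates:
            if (i, j) in occupied:
                continue
            disp = math.hypot(i * pitch - x, j * pitch - y)
            if disp > max_disp + 1e-12:
                break
            occupied.add((i, j))
            out[idx, 0], out[idx, 1] = i * pitch, j * pitch
            placed = True
            break
        if not placed:
            raise InfeasibleGeometryError(
                f"cannot place element {idx} on the {pitch} mm grid within one "
                "grid diagonal; pitch too coarse for this spiral density"
            )
    return out


def sparsify(layout: ElementLayout, k: int) -> ElementLayout:
    """Return the k outermost elements of ``layout`` (element_id order preserved)."""
    n = layout.n_elements
    if not MIN_ELEMENTS <= k <= n:
        raise InvalidSubsetError(f"subset size must be in [{MIN_ELEMENTS}, {n}], got {k}")
    keep = layout.radial_rank >= n - k
    return ElementLayout(
        element_ids=layout.element_ids[keep],
        positions=layout.positions[keep],
    )


def build_plan(layout: ElementLayout, sizes) -> SparsificationPlan:
    """Build a nested sparsification plan for the given descending sizes."""
    sizes = [int(s) for s in sizes]
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise InvalidPlanError(f"sizes must be strictly descending, got {sizes}")
    n = layout.n_elements
    if any(not MIN_ELEMENTS <= s <= n for s in sizes):
        raise InvalidPlanError(f"every size must be in [{MIN_ELEMENTS}, {n}], got {sizes}")
    subsets = {s: sparsify(layout, s).element_ids for s in sizes}
    return SparsificationPlan(subset_sizes=tuple(sizes), subsets=subsets)


def default_layout(
    n_elements: int = 256, scale: float = 0.33, pitch: float | None = 0.3
) -> ElementLayout:
    """The default 256-element spiral used throughout the package.

    The scale puts the outermost radius at ≈ 5.3 mm, about half the aperture
    of a 32×35-element matrix array at 0.3 mm pitch.
    """
    return generate_fermat_spiral(n_elements, scale, pitch)
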