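"""Spatial topology of the capture array.

A capture grid partitions the measured locations into *inner* (saturated)
points — those with the maximal number of neighbors the platform allows —
and *boundary* points.  Neighborhoods are Euclidean balls of radius ``d_P``
(the platform spacing) on structured arrays, and mutualized k-nearest
neighbors on unstructured (bead/point-cloud) platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, InvalidInputError, InvalidParameterError

TOPOLOGIES = ("rectilinear", "hexagonal", "unstructured")

#: Maximal neighbor count per structured platform.
MAX_NEIGHBORS = {"rectilinear": 4, "hexagonal": 6}

#: Multiplier applied to the minimum nearest-neighbor distance when the
#: spacing is auto-estimated; absorbs floating-point jitter in position files.
SPACING_TOLERANCE = 1.05


@dataclass
class CaptureGrid:
    """Capture-location coordinates plus derived neighborhood structure.

    Attributes
    ----------
    coords
        ``(n, 2)`` float array of x/y positions in platform units.
    topology
        One of ``rectilinear``, ``hexagonal``, ``unstructured``.
    spacing
        Neighbor-ball radius ``d_P`` (structured) or the mean neighbor
        distance scale (unstructured).
    max_neighbors
        Saturation threshold ``M_P``: 4 (rectilinear), 6 (hexagonal), or the
        configured ``k`` (unstructured).
    neighbor_index
        Per location, a sorted integer array of neighbor indices.
    inner_mask
        Boolean per location; True where ``|N(s)| == M_P``.
    nearest_inner
        Per location, the index of the nearest inner point (ties broken by
        lowest index); ``-1`` where no inner point exists.  Defined for
        every location, though only boundary points consume it.
    """

    coords: np.ndarray
    topology: str
    spacing: float
    max_neighbors: int
    neighbor_index: list[np.ndarray]
    inner_mask: np.ndarray
    nearest_inner: np.ndarray
    no_inner_warning: bool = False
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_locations(self) -> int:
        return self.coords.shape[0]

    @property
    def boundary_mask(self) -> np.ndarray:
        return ~self.inner_mask

    @property
    def inner_indices(self) -> np.ndarray:
        return np.flatnonzero(self.inner_mask)

    @property
    def n_inner(self) -> int:
        return int(self.inner_mask.sum())


def _pairs_to_index(n: int, pairs: np.ndarray) -> list[np.ndarray]:
    neigh: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        neigh[a].append(b)
        neigh[b].append(a)
    return [np.array(sorted(s), dtype=np.intp) for s in neigh]


def _ball_neighbors(coords: np.ndarray, radius: float) -> list[np.ndarray]:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    return _pairs_to_index(len(coords), pairs)


def _mutual_knn_neighbors(coords: np.ndarray, k: int) -> list[np.ndarray]:
    n = len(coords)
    tree = cKDTree(coords)
    k_eff = min(k + 1, n)
    _, idx = tree.query(coords, k=k_eff)
    idx = np.atleast_2d(idx)
    knn_sets = [set(row[1:]) for row in idx]  # row[0] is the point itself
    pairs = []
    for s in range(n):
        for q in knn_sets[s]:
            if q > s and s in knn_sets[q]:
                pairs.append((s, q))
    return _pairs_to_index(n, np.array(pairs, dtype=np.intp).reshape(-1, 2))


def estimate_spacing(coords: np.ndarray) -> float:
    """Auto spacing: 1.05 x the minimum positive nearest-neighbor distance."""
    tree = cKDTree(coords)
    k = min(len(coords), 8)
    dists, _ = tree.query(coords, k=k)
    positive = dists[:, 1:][dists[:, 1:] > 0]
    if positive.size == 0:
        raise DegenerateGeometryError("all capture locations are coincident")
    return SPACING_TOLERANCE * float(positive.min())


def build_grid(
    coords: Sequence | np.ndarray,
    topology: str = "rectilinear",
    spacing: float | None = None,
    k: int = 6,
) -> CaptureGrid:
    """Build the neighbor index and inner/boundary partition for a platform.

    Parameters
    ----------
    coords
        ``(n, 2)`` positions of the capture locations.
    topology
        ``rectilinear`` (ST-style arrays, M_P=4), ``hexagonal`` (Visium,
        M_P=6) or ``unstructured`` (bead platforms; mutual k-NN graph).
    spacing
        Neighbor-ball radius ``d_P``.  ``None`` auto-estimates it from the
        minimum positive nearest-neighbor distance.
    k
        Neighbor count for the unstructured topology (ignored otherwise).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InvalidInputError(f"coords must be (n, 2); got shape {coords.shape}")
    if coords.shape[0] < 2:
        raise InvalidInputError("at least 2 capture locations are required")
    if not np.all(np.isfinite(coords)):
        raise InvalidInputError("coordinates must be finite")
    if len(np.unique(coords, axis=0)) < 2:
        raise DegenerateGeometryError("all capture locations are coincident")
    if topology not in TOPOLOGIES:
        raise InvalidParameterError(f"unknown topology {topology!r}")

    if spacing is None:
        spacing = estimate_spacing(coords)
    elif spacing <= 0:
        raise InvalidParameterError("spacing must be positive")

    if topology == "unstructured":
        if k < 1:
            raise InvalidParameterError("k must be >= 1")
        max_neighbors = k
        neighbor_index = _mutual_knn_neighbors(coords, k)
    else:
        max_neighbors = MAX_NEIGHBORS[topology]
        neighbor_index = _ball_neighbors(coords, spacing)

    counts = np.array([len(s) for s in neighbor_index])
    inner_mask = counts == max_neighbors
    if np.any(counts > max_neighbors):
        raise InvalidInputError(
            "some locations have more neighbors than the platform maximum "
            f"({counts.max()} > {max_neighbors}); check spacing/topology"
        )

    grid = CaptureGrid(
        coords=coords,
        topology=topology,
        spacing=float(spacing),
        max_neighbors=int(max_neighbors),
        neighbor_index=neighbor_index,
        inner_mask=inner_mask,
        nearest_inner=np.full(len(coords), -1, dtype=np.intp),
    )
    if inner_mask.any():
        inner_idx = np.flatnonzero(inner_mask)
        # argmin returns the first minimum: ties resolve to the lowest index.
        d = cdist(coords, coords[inner_idx])
        grid.nearest_inner = inner_idx[np.argmin(d, axis=1)]
    else:
        grid.no_inner_warning = True
        warnings.warn(
            "grid has zero inner (saturated) points; the boundary rule "
            "degenerates and every profile converges immediately",
            stacklevel=2,
        )
    return grid


def nearest_inner_map(grid: CaptureGrid) -> dict[int, int]:
    """Map each boundary location to its nearest inner location.

    Ties are broken by the lowest inner-point index.  Returns an empty
    mapping (with a warning) when the grid has no inner points.
    """
    if not grid.inner_mask.any():
        warnings.warn("grid has no inner points; empty mapping", stacklevel=2)
        return {}
    return {
        int(b): int(grid.nearest_inner[b])
        for b in np.flatnonzero(grid.boundary_mask)
    }


def rectilinear_lattice(n_rows: int, n_cols: int) -> np.ndarray:
    """Integer-lattice coordinates, row-major, unit spacing."""
    ys, xs = np.mgrid[0:n_rows, 0:n_cols]
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def hexagonal_lattice(n_rows: int, n_cols: int) -> np.ndarray:
    """Axial hex lattice: odd rows offset by half a column, row pitch sqrt(3)/2.

    Every interior point has exactly 6 neighbors at unit distance, matching
    the Visium spot arrangement.
    """
    coords = []
    for r in range(n_rows):
        for c in range(n_cols):
            coords.append((c + 0.5 * (r % 2), r * np.sqrt(3) / 2))
    return np.asarray(coords, dtype=float)
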