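"""Diffusion-time ranking engine.

Each normalized transcript profile ``u`` is treated as the initial
condition of the heat equation du/dt = D * Lap(u) on the capture grid and
propagated with explicit forward-Euler steps.  The Laplacian is a
finite-difference stencil chosen by grid topology; boundary points are
handled by one of two rules (see ``DiffusionParams.boundary``): the
conservative ``zero-flux`` default, where each boundary point relaxes
through its own reduced neighbor set, or ``nearest-inner``, where a
boundary point adopts the Laplacian of its nearest inner point.  The
zero-flux operator keeps the inner-point entropy monotone, which makes
the convergence criterion below well-posed; the nearest-inner rule is
retained as an option.  After every step the Shannon
entropy of the field over the inner points is computed; the simulation
stops when the entropy change per step drops below ``eps * |S_i|``.  The
elapsed simulated time — the *diffusion time* t_d — is the ranking metric:
spatially organized profiles take longer to homogenize than random ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from joblib import Parallel, delayed
from scipy.special import xlogy

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    NumericalInstabilityError,
    TopologyMismatchError,
    UndefinedEntropyError,
)
from .grid import CaptureGrid
from .preprocessing import ProfileMatrix

#: Safety factor on the forward-Euler stability bound used for the auto dt.
DT_SAFETY = 0.1

#: Normalized-value range below which the sorted diffusion-time curve is
#: considered flat and the selection heuristic returns nothing.
FLAT_CURVE_RANGE = 1e-6


@dataclass
class DiffusionParams:
    """Tunable parameters of the propagation and convergence test.

    ``dt = None`` auto-selects ``0.1 * h^2 / (4 D)`` where ``h`` is the grid
    step length — one tenth of the classic forward-Euler stability bound.
    ``eps`` is the admissible entropy change per inner point per step.
    """

    D: float = 1.0
    dt: float | None = None
    eps: float = 1e-8
    max_steps: int = 100_000
    entropy_floor: float = 0.0
    boundary: str = "zero-flux"

    def __post_init__(self):
        if self.D < 0:
            raise InvalidParameterError("D must be >= 0")
        if self.boundary not in ("zero-flux", "nearest-inner"):
            raise InvalidParameterError(
                f"boundary must be 'zero-flux' or 'nearest-inner'; got {self.boundary!r}"
            )
        if self.dt is not None and self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.eps <= 0:
            raise InvalidParameterError("eps must be positive")
        if self.max_steps < 1:
            raise InvalidParameterError("max_steps must be >= 1")

    def resolve_dt(self, grid: CaptureGrid) -> float:
        if self.dt is not None:
            return self.dt
        h = _step_length(grid)
        d = self.D if self.D > 0 else 1.0
        return DT_SAFETY * h * h / (4.0 * d)


@dataclass
class DiffusionResult:
    """Per-gene diffusion times, normalized values and ranks."""

    gene_names: np.ndarray
    t_d: np.ndarray
    t_d_normalized: np.ndarray
    rank: np.ndarray
    converged: np.ndarray
    steps: np.ndarray
    dt: float = field(default=np.nan)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


# ---------------------------------------------------------------------------
# Laplacian stencils
# ---------------------------------------------------------------------------

def _step_length(grid: CaptureGrid) -> float:
    """Mean distance from inner points to their neighbors (lattice pitch)."""
    if "h" not in grid._cache:
        inner = grid.inner_indices
        if inner.size == 0:
            grid._cache["h"] = grid.spacing
        else:
            dists = [
                np.linalg.norm(grid.coords[grid.neighbor_index[s]] - grid.coords[s], axis=1)
                for s in inner
            ]
            grid._cache["h"] = float(np.concatenate(dists).mean())
    return grid._cache["h"]


def _stencil_matrix(grid: CaptureGrid) -> sp.csr_matrix:
    """Sparse Laplacian with one row per location, reduced at the boundary.

    Inner rows apply the full platform stencil:

    rectilinear:  (sum of 4 neighbors - 4 u) / h^2
    hexagonal:    (2 / (3 h^2)) (sum of 6 neighbors - 6 u)
    unstructured: (4 / hbar_s^2) * mean_q (u_q - u_s), with hbar_s the mean
                  neighbor distance of s — reduces to the two stencils above
                  on perfect lattices.

    Boundary rows use the same per-edge weights over the neighbors the point
    actually has (zero-flux closure); isolated points contribute 0.
    """
    if "stencil" in grid._cache:
        return grid._cache["stencil"]
    n = grid.n_locations
    rows, cols, vals = [], [], []
    h = _step_length(grid)
    for s in range(n):
        neigh = grid.neighbor_index[s]
        if len(neigh) == 0:
            continue
        if grid.topology == "rectilinear":
            w = 1.0 / (h * h)
        elif grid.topology == "hexagonal":
            w = 2.0 / (3.0 * h * h)
        else:
            hbar = float(
                np.linalg.norm(grid.coords[neigh] - grid.coords[s], axis=1).mean()
            )
            w = 4.0 / (len(neigh) * hbar * hbar)
        for q in neigh:
            rows.append(s)
            cols.append(q)
            vals.append(w)
        rows.append(s)
        cols.append(s)
        vals.append(-w * len(neigh))
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    grid._cache["stencil"] = L
    return L


def _full_laplacian(grid: CaptureGrid, boundary: str = "zero-flux") -> sp.csr_matrix:
    """Whole-grid diffusion operator for the requested boundary rule.

    ``zero-flux``: every point, boundary included, relaxes through its own
    neighbor set (conservative; positivity-preserving at a stable dt).
    ``nearest-inner``: boundary rows are replaced by a copy of the nearest
    inner point's stencil row, so each boundary point is updated with that
    inner point's Laplacian value.
    """
    key = f"full_lap:{boundary}"
    if key in grid._cache:
        return grid._cache[key]
    L = _stencil_matrix(grid)
    if boundary == "zero-flux":
        full = L
    elif grid.n_inner == 0:
        full = sp.csr_matrix(L.shape)
    else:
        gather = np.where(grid.inner_mask, np.arange(grid.n_locations), grid.nearest_inner)
        full = L[gather, :].tocsr()
    grid._cache[key] = full
    return full


def _check_topology(grid: CaptureGrid, expected: str) -> None:
    if grid.topology != expected:
        raise TopologyMismatchError(
            f"stencil for {expected!r} applied to a {grid.topology!r} grid"
        )


def laplacian_rectilinear(u: np.ndarray, grid: CaptureGrid) -> np.ndarray:
    """Five-point stencil Laplacian, returned over the inner points only."""
    _check_topology(grid, "rectilinear")
    return (_stencil_matrix(grid) @ np.asarray(u, dtype=float))[grid.inner_indices]


def laplacian_hexagonal(u: np.ndarray, grid: CaptureGrid) -> np.ndarray:
    """Seven-point hexagonal stencil Laplacian over the inner points."""
    _check_topology(grid, "hexagonal")
    return (_stencil_matrix(grid) @ np.asarray(u, dtype=float))[grid.inner_indices]


def laplacian_unstructured(u: np.ndarray, grid: CaptureGrid) -> np.ndarray:
    """Graph-Laplacian approximation over the inner points of a point cloud."""
    _check_topology(grid, "unstructured")
    return (_stencil_matrix(grid) @ np.asarray(u, dtype=float))[grid.inner_indices]


# ---------------------------------------------------------------------------
# Propagation and entropy
# ---------------------------------------------------------------------------

def propagate(
    u: np.ndarray, grid: CaptureGrid, params: DiffusionParams | None = None
) -> np.ndarray:
    """One synchronous forward-Euler step: u + D * Lap(u) * dt.

    Inner points use their own stencil Laplacian; each boundary point uses
    the Laplacian value of its nearest inner point.  All Laplacians are
    evaluated on the state at time t.
    """
    params = params or DiffusionParams()
    u = np.asarray(u, dtype=float)
    dt = params.resolve_dt(grid)
    out = u + params.D * dt * (_full_laplacian(grid, params.boundary) @ u)
    if not np.all(np.isfinite(out)):
        raise NumericalInstabilityError(
            f"NaN/Inf in the diffusion state; reduce dt (current dt={dt:g})"
        )
    # transcript concentrations are non-negative; the nearest-inner boundary
    # rule is not positivity-preserving, so clamp (no-op while u stays >= 0)
    return np.maximum(out, 0.0)


def entropy(u: np.ndarray, subset: np.ndarray | None = None) -> float:
    """Shannon entropy (natural log) of u normalized over ``subset``.

    ``u_hat = u / sum(u)`` over the subset; ``H = -sum(u_hat ln u_hat)``
    with the convention 0 ln 0 = 0.
    """
    u = np.asarray(u, dtype=float)
    v = u if subset is None else u[np.asarray(subset)]
    if v.size == 0:
        raise UndefinedEntropyError("entropy of an empty subset is undefined")
    if np.any(v < 0):
        raise InvalidInputError("entropy requires non-negative values")
    total = v.sum()
    if total <= 0:
        raise UndefinedEntropyError("entropy undefined: subset has zero total mass")
    p = v / total
    return float(-xlogy(p, p).sum())


def _entropy_columns(V: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Entropy of each column of a (locations x genes) block."""
    V = np.clip(V, floor, None)
    totals = V.sum(axis=0)
    if np.any(totals <= 0):
        raise UndefinedEntropyError("entropy undefined: zero total mass over inner points")
    P = V / totals
    return -xlogy(P, P).sum(axis=0)


def _diffusion_times_batch(
    U0: np.ndarray, grid: CaptureGrid, params: DiffusionParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diffusion time for each row of U0 (genes x locations).

    Genes are propagated jointly but converge independently; a gene's
    column is frozen and removed once its entropy change falls below the
    threshold.  Returns (t_d, steps, converged).
    """
    U0 = np.atleast_2d(np.asarray(U0, dtype=float))
    n_genes = U0.shape[0]
    dt = params.resolve_dt(grid)
    steps_out = np.full(n_genes, params.max_steps, dtype=np.int64)
    converged = np.zeros(n_genes, dtype=bool)

    if grid.n_inner == 0:
        warnings.warn(
            "grid has no inner points; all profiles converge at step 1",
            stacklevel=2,
        )
        return np.full(n_genes, dt), np.ones(n_genes, dtype=np.int64), np.ones(n_genes, dtype=bool)

    inner = grid.inner_indices
    threshold = params.eps * inner.size
    A = (sp.identity(grid.n_locations, format="csr")
         + params.D * dt * _full_laplacian(grid, params.boundary)).tocsr()

    U = np.ascontiguousarray(U0.T)  # locations x genes
    active = np.arange(n_genes)
    H_prev = _entropy_columns(U[inner], params.entropy_floor)

    for step in range(1, params.max_steps + 1):
        U = np.maximum(A @ U, 0.0)  # positivity: boundary rule can undershoot
        if not np.all(np.isfinite(U)):
            raise NumericalInstabilityError(
                f"NaN/Inf during propagation at step {step}; reduce dt (dt={dt:g})"
            )
        H = _entropy_columns(U[inner], params.entropy_floor)
        done = np.abs(H - H_prev) < threshold
        if done.any():
            steps_out[active[done]] = step
            converged[active[done]] = True
            keep = ~done
            active = active[keep]
            if active.size == 0:
                break
            U = np.ascontiguousarray(U[:, keep])
            H_prev = H[keep]
        else:
            H_prev = H

    return steps_out * dt, steps_out, converged


def diffusion_time(
    u0: np.ndarray, grid: CaptureGrid, params: DiffusionParams | None = None
) -> tuple[float, int, bool]:
    """Diffusion time of a single normalized profile.

    Returns ``(t_d, steps, converged)``; ``t_d = steps * dt``.  If the
    entropy change never falls below ``eps * |S_i|`` within ``max_steps``,
    the profile is reported non-converged with ``t_d = max_steps * dt``.
    """
    params = params or DiffusionParams()
    t, s, c = _diffusion_times_batch(np.atleast_2d(u0), grid, params)
    return float(t[0]), int(s[0]), bool(c[0])


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map values to [0, 1]: subtract the minimum, divide by the range.

    A zero range (all values equal) maps everything to 0 with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        warnings.warn("all diffusion times equal; normalized values set to 0", stacklevel=2)
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def dense_ranks(values: np.ndarray) -> np.ndarray:
    """Dense descending ranks: the largest value gets rank 1, ties share."""
    values = np.asarray(values)
    uniq = np.unique(values)
    return (len(uniq) - np.searchsorted(uniq, values)).astype(int)


def rank_by_diffusion(
    matrix: ProfileMatrix,
    grid: CaptureGrid,
    params: DiffusionParams | None = None,
    n_workers: int = 1,
) -> DiffusionResult:
    """Compute, normalize and rank diffusion times for every gene.

    Genes are independent, so they are evaluated in parallel chunks with
    bit-identical results regardless of ``n_workers``.  Diffusion times are
    minmax-normalized across genes and converted to dense ranks (highest
    t_d = rank 1, ties share a rank).
    """
    params = params or DiffusionParams()
    if matrix.n_locations != grid.n_locations:
        raise InvalidInputError(
            f"matrix has {matrix.n_locations} locations but grid has {grid.n_locations}"
        )
    if matrix.n_genes == 0:
        empty = np.array([])
        return DiffusionResult(
            gene_names=np.array([], dtype=object),
            t_d=empty, t_d_normalized=empty,
            rank=np.array([], dtype=int),
            converged=np.array([], dtype=bool),
            steps=np.array([], dtype=int),
            dt=params.resolve_dt(grid),
        )
    if matrix.degenerate is not None and np.any(matrix.degenerate):
        raise InvalidInputError(
            "matrix contains degenerate (all-zero normalized) genes; "
            "apply filter_genes or use a pseudocount > 1 before ranking"
        )

    U0 = matrix.normalized
    if n_workers <= 1 or matrix.n_genes < 2 * n_workers:
        t_d, steps, converged = _diffusion_times_batch(U0, grid, params)
    else:
        chunks = np.array_split(np.arange(matrix.n_genes), n_workers)
        parts = Parallel(n_jobs=n_workers)(
            delayed(_diffusion_times_batch)(U0[c], grid, params)
            for c in chunks if c.size
        )
        t_d = np.concatenate([p[0] for p in parts])
        steps = np.concatenate([p[1] for p in parts])
        converged = np.concatenate([p[2] for p in parts])

    t_norm = minmax_normalize(t_d)
    rank = dense_ranks(t_d)
    return DiffusionResult(
        gene_names=matrix.gene_names.copy(),
        t_d=t_d,
        t_d_normalized=t_norm,
        rank=rank.astype(int),
        converged=converged,
        steps=steps,
        dt=params.resolve_dt(grid),
    )


def select_top(result: DiffusionResult) -> list[str]:
    """Knee-point heuristic selecting the distinctly high-ranked profiles.

    Sorts normalized diffusion times descending and finds the index
    maximizing the perpendicular distance to the chord from the first to
    the last point (both axes scaled to [0, 1]); genes above the knee are
    returned.  Conservative by construction: a flat curve (range below
    1e-6) or a collinear descent selects nothing.
    """
    if result.n_genes < 3:
        raise InvalidInputError("top-profile selection requires at least 3 genes")
    order = np.lexsort((result.gene_names, -result.t_d_normalized))
    v = result.t_d_normalized[order]
    if v[0] - v[-1] < FLAT_CURVE_RANGE:
        return []
    n = len(v)
    x = np.linspace(0.0, 1.0, n)
    y = (v - v[-1]) / (v[0] - v[-1])
    # perpendicular distance to the chord from (0, y0) to (1, y_last)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([x, y]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    if dist.max() < 1e-9:
        return []
    knee = int(np.argmax(dist))
    return [str(g) for g in result.gene_names[order[:knee]]]
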