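"""Synthetic validation data with ground-truth structure labels.

Two benchmark constructions:

* *mixed sets* — structured parent profiles plus offspring obtained by
  multiplying a parent with a factor and randomly shuffling the values
  across locations; a ranking method should place every parent above
  every offspring.
* *ablation sets* — one structured profile perturbed by shuffling an
  increasing number of observations in place, carrying an innate internal
  ordering of spatial structure.

Seed profiles come either from binary images (white = elevated
expression) or from a Gray-Scott reaction-diffusion simulation, whose
spot/stripe steady states provide organically structured patterns from
random initial conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import scipy.sparse as sp

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    NumericalInstabilityError,
)
from .grid import CaptureGrid
from .preprocessing import ProfileMatrix

DEFAULT_MULTIPLIERS = (0.5, 1.0, 2.0)
DEFAULT_N_OFFSPRING = 3
DEFAULT_ABLATION_STAGES = (0, 100, 500, 900)


@dataclass
class GrayScottParams:
    """Gray-Scott reaction-diffusion settings (spot-forming regime).

    du/dt = Du Lap(u) - u v^2 + F (1 - u)
    dv/dt = Dv Lap(v) + u v^2 - (F + kill) v
    """

    F: float = 0.0545
    kill: float = 0.062
    Du: float = 0.16
    Dv: float = 0.08
    dt: float = 1.0
    steps: int = 5000
    amplitude: float = 50.0  # count-like scale of the returned field


@dataclass
class SyntheticSet:
    """Generated profiles plus the provenance labels used in evaluation.

    ``labels`` has one row per profile: columns ``profile``, ``parent_id``,
    ``multiplier``, ``is_parent`` (mixed) or ``profile``, ``n_shuffled``
    (ablation).
    """

    kind: str  # "mixed" | "ablation"
    profiles: ProfileMatrix
    labels: pd.DataFrame
    seed: int
    grid: CaptureGrid


def binary_image_bank(size: int = 64) -> list[np.ndarray]:
    """Ten procedurally generated binary masks with distinct spatial structure.

    Synthetic stand-ins for hand-drawn expression-region images: half
    planes, a disc, a ring, diagonal and axis-aligned bands, blobs and a
    quadrant.  Each mask is a ``size x size`` boolean raster suitable for
    :func:`image_seed`.
    """
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - size / 2, yy - size / 2)
    masks = [
        xx < size // 2,                                   # left half
        yy < size // 2,                                   # top half
        r < size * 0.28,                                  # centered disc
        (r > size * 0.18) & (r < size * 0.33),            # ring
        np.abs(xx - yy) < size * 0.15,                    # diagonal band
        (np.hypot(xx - size * 0.3, yy - size * 0.3) < size * 0.16)
        | (np.hypot(xx - size * 0.72, yy - size * 0.7) < size * 0.16),  # two blobs
        (xx < size // 2) & (yy < size // 2),              # quadrant
        np.abs(xx - size * 0.5) < size * 0.12,            # vertical stripe
        np.abs(yy - size * 0.33) < size * 0.14,           # horizontal band
        np.hypot(xx - size * 0.25, yy - size * 0.7) < size * 0.22,      # corner blob
    ]
    return [m.astype(bool) for m in masks]


def _neumann_laplacian(grid: CaptureGrid) -> sp.csr_matrix:
    """Unit-weight graph Laplacian over all locations (zero-flux boundary).

    Each point, boundary included, diffuses through its own neighbor set —
    the natural closed-domain operator for the reaction-diffusion
    simulation (the ranking engine's nearest-inner boundary rule would
    inject spurious flux here and destabilize the dynamics).
    """
    key = "neumann_lap"
    if key not in grid._cache:
        rows, cols, vals = [], [], []
        for s in range(grid.n_locations):
            neigh = grid.neighbor_index[s]
            for q in neigh:
                rows.append(s)
                cols.append(q)
                vals.append(1.0)
            rows.append(s)
            cols.append(s)
            vals.append(-float(len(neigh)))
        grid._cache[key] = sp.csr_matrix(
            (vals, (rows, cols)), shape=(grid.n_locations, grid.n_locations)
        )
    return grid._cache[key]


def turing_seed(
    grid: CaptureGrid,
    params: GrayScottParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a Gray-Scott system on the grid and return a count-like field.

    The activator species v, which concentrates into spots in the default
    regime, is shifted to be non-negative, scaled to ``amplitude`` and
    rounded to integers.  ``steps = 0`` returns the (scaled) random initial
    state.
    """
    params = params or GrayScottParams()
    rng = np.random.default_rng(seed)
    n = grid.n_locations

    u = 1.0 + 0.02 * rng.uniform(-1.0, 1.0, n)
    v = 0.01 * rng.uniform(0.0, 1.0, n)
    # seed reaction patches at random locations to nucleate patterns
    n_patches = max(1, n // 100)
    centers = rng.choice(n, size=n_patches, replace=False)
    radius = 1.5 * grid.spacing
    for c in centers:
        near = np.linalg.norm(grid.coords - grid.coords[c], axis=1) <= radius
        u[near] = 0.5
        v[near] = 0.25 + 0.05 * rng.uniform(0.0, 1.0, near.sum())

    L = _neumann_laplacian(grid)
    for _ in range(params.steps):
        uvv = u * v * v
        lu = L @ u
        lv = L @ v
        u = u + params.dt * (params.Du * lu - uvv + params.F * (1.0 - u))
        v = v + params.dt * (params.Dv * lv + uvv - (params.F + params.kill) * v)
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise NumericalInstabilityError(
                "Gray-Scott dynamics diverged; reduce dt or diffusion rates"
            )

    w = v - v.min()
    peak = w.max()
    if peak > 0:
        w = w / peak * params.amplitude
    return np.rint(w).astype(np.int64)


def image_seed(
    image,
    grid: CaptureGrid,
    high: int = 10,
    low: int = 0,
    poisson_jitter: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Sample a black-and-white image onto the grid.

    White pixels mark regions of elevated expression (``high``), black
    regions background (``low``).  ``image`` is a 2-D boolean/grayscale
    array or a path readable by Pillow.  Each capture location samples the
    pixel it falls on within the grid's bounding box.
    """
    if isinstance(image, (str, Path)):
        from PIL import Image

        try:
            img = np.asarray(Image.open(image).convert("L"))
        except OSError as e:
            raise InvalidInputError(f"cannot read image {image!r}: {e}") from e
    else:
        img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise InvalidInputError("image must be a non-empty 2-D raster")
    white = img > 127 if img.dtype != bool else img

    h, w = white.shape
    x, y = grid.coords[:, 0], grid.coords[:, 1]
    xspan = x.max() - x.min() or 1.0
    yspan = y.max() - y.min() or 1.0
    cols = np.minimum((np.floor((x - x.min()) / xspan * w)).astype(int), w - 1)
    # image row 0 is the top of the picture = largest y
    rows = np.minimum((np.floor((y.max() - y) / yspan * h)).astype(int), h - 1)

    field = np.where(white[rows, cols], high, low).astype(np.int64)
    if poisson_jitter:
        rng = np.random.default_rng(seed)
        field = rng.poisson(np.maximum(field, 0)).astype(np.int64)
    return field


def assemble_mixed(
    seeds: list[np.ndarray],
    grid: CaptureGrid,
    multipliers=DEFAULT_MULTIPLIERS,
    n_offspring: int = DEFAULT_N_OFFSPRING,
    seed: int = 0,
) -> SyntheticSet:
    """Mixed set: each parent plus shuffled, multiplied offspring.

    For every parent p_i: include p_i unshuffled; then for each multiplier
    m_j, ``n_offspring`` times, round p_i * m_j to integers and permute the
    values across locations.  With 10 seeds and the defaults this yields
    10 + 10*3*3 = 100 profiles, 10 of them parents.
    """
    if not seeds:
        raise InvalidInputError("at least one seed profile is required")
    multipliers = tuple(float(m) for m in multipliers)
    if any(m <= 0 for m in multipliers):
        raise InvalidParameterError("multipliers must be positive")
    if n_offspring < 1:
        raise InvalidParameterError("n_offspring must be >= 1")

    rng = np.random.default_rng(seed)
    n_loc = grid.n_locations
    profiles, names, rows = [], [], []
    for i, p in enumerate(seeds):
        p = np.asarray(p)
        if p.shape != (n_loc,):
            raise InvalidInputError(
                f"seed {i} has shape {p.shape}; expected ({n_loc},)"
            )
        name = f"parent_{i}"
        profiles.append(np.rint(p).astype(np.int64))
        names.append(name)
        rows.append((name, i, 1.0, True))
        for m in multipliers:
            w = np.rint(p * m).astype(np.int64)
            for f in range(n_offspring):
                child = w[rng.permutation(n_loc)]
                cname = f"offspring_{i}_m{m:g}_{f}"
                profiles.append(child)
                names.append(cname)
                rows.append((cname, i, m, False))

    labels = pd.DataFrame(rows, columns=["profile", "parent_id", "multiplier", "is_parent"])
    return SyntheticSet(
        kind="mixed",
        profiles=ProfileMatrix.from_raw(np.vstack(profiles), names),
        labels=labels,
        seed=seed,
        grid=grid,
    )


def assemble_ablation(
    seed_field: np.ndarray,
    grid: CaptureGrid,
    stages=DEFAULT_ABLATION_STAGES,
    seed: int = 0,
    name_prefix: str = "ablation",
) -> SyntheticSet:
    """Ablation set: one profile at increasing degrees of in-place shuffling.

    For each stage n, n locations are chosen uniformly without replacement
    and their values permuted among themselves; the remaining locations are
    untouched.  Stage 0 is the unperturbed seed.
    """
    seed_field = np.rint(np.asarray(seed_field)).astype(np.int64)
    n_loc = grid.n_locations
    if seed_field.shape != (n_loc,):
        raise InvalidInputError(
            f"seed field has shape {seed_field.shape}; expected ({n_loc},)"
        )
    stages = [int(s) for s in stages]
    if stages[0] != 0 or any(b <= a for a, b in zip(stages, stages[1:])):
        raise InvalidParameterError("stages must be strictly increasing from 0")
    if max(stages) > n_loc:
        raise InvalidParameterError(
            f"stage {max(stages)} exceeds the {n_loc} available locations"
        )

    rng = np.random.default_rng(seed)
    profiles, names, rows = [], [], []
    for n in stages:
        field = seed_field.copy()
        if n > 0:
            idx = rng.choice(n_loc, size=n, replace=False)
            field[idx] = field[idx][rng.permutation(n)]
        name = f"{name_prefix}_shuf{n}"
        profiles.append(field)
        names.append(name)
        rows.append((name, n))

    labels = pd.DataFrame(rows, columns=["profile", "n_shuffled"])
    return SyntheticSet(
        kind="ablation",
        profiles=ProfileMatrix.from_raw(np.vstack(profiles), names),
        labels=labels,
        seed=seed,
        grid=grid,
    )
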