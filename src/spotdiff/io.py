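"""Readers and writers for the spatial formats the tool touches.

Supported inputs: ST-style TSV count tables with ``XxY`` coordinate
headers (rectilinear arrays), Visium-style directories (Matrix Market
counts + barcodes + features + tissue positions; hexagonal), and generic
wide tables with explicit x/y columns (unstructured platforms).  Results
are persisted as TSV (per-gene tables) and JSON (reports).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .diffusion import DiffusionResult
from .errors import InvalidInputError
from .families import PatternFamilySet
from .grid import CaptureGrid, build_grid
from .preprocessing import DEFAULT_PSEUDOCOUNT, ProfileMatrix

_COORD_RE = re.compile(r"^\s*([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)x([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)\s*$")

#: Visium array row pitch in column units (spots on a triangular lattice).
HEX_ROW_PITCH = np.sqrt(3) / 2


@dataclass
class Dataset:
    """A profile matrix tied to its capture grid plus provenance."""

    matrix: ProfileMatrix
    grid: CaptureGrid
    source: str = ""
    platform: str = ""
    filters: dict = field(default_factory=dict)


def parse_coordinate_header(token: str) -> tuple[float, float]:
    m = _COORD_RE.match(str(token))
    if not m:
        raise InvalidInputError(
            f"malformed coordinate header {token!r}; expected '<x>x<y>' like '12.5x3.0'"
        )
    return float(m.group(1)), float(m.group(2))


def read_st_tsv(
    path,
    transpose: bool = False,
    topology: str = "rectilinear",
    c: float = DEFAULT_PSEUDOCOUNT,
) -> Dataset:
    """Read an ST-style TSV count matrix with ``XxY`` coordinate labels.

    By default genes are rows and locations are columns (coordinate labels
    in the header); ``transpose=True`` reads the dialect with locations as
    rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    coords = np.array([parse_coordinate_header(t) for t in df.columns])
    matrix = ProfileMatrix.from_raw(
        df.to_numpy(dtype=float), [str(g) for g in df.index], c=c
    )
    grid = build_grid(coords, topology=topology)
    return Dataset(matrix=matrix, grid=grid, source=str(path), platform="ST")


def write_st_tsv(matrix: ProfileMatrix, grid: CaptureGrid, path) -> None:
    """Write counts as a TSV with locations as rows labeled ``XxY``."""
    labels = [f"{x:g}x{y:g}" for x, y in grid.coords]
    df = pd.DataFrame(
        matrix.raw.T, index=labels, columns=[str(g) for g in matrix.gene_names]
    )
    df.to_csv(path, sep="\t", index_label="coordinates")


def visium_array_to_xy(array_row: np.ndarray, array_col: np.ndarray) -> np.ndarray:
    """Convert Visium array indices to hex-lattice x/y.

    Columns step by 2 within a row (odd rows hold odd columns), so halving
    the column index and scaling rows by sqrt(3)/2 yields a triangular
    lattice where each interior spot has 6 neighbors at unit distance.
    """
    return np.column_stack([array_col * 0.5, array_row * HEX_ROW_PITCH])


def read_visium(dir_path, c: float = DEFAULT_PSEUDOCOUNT) -> Dataset:
    """Read a Visium-style directory restricted to in-tissue spots.

    Expects ``matrix.mtx`` (genes x barcodes), ``features.tsv``,
    ``barcodes.tsv`` and ``tissue_positions.csv`` (or
    ``tissue_positions_list.csv``).
    """
    d = Path(dir_path)

    def _find(*names: str) -> Path:
        for name in names:
            p = d / name
            if p.exists():
                return p
        raise FileNotFoundError(f"missing {names[0]} in {d}")

    mat = sp.csr_matrix(scipy.io.mmread(_find("matrix.mtx")))
    features = pd.read_csv(_find("features.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(_find("barcodes.tsv"), sep="\t", header=None)[0].astype(str)
    pos_path = _find("tissue_positions.csv", "tissue_positions_list.csv")
    pos = pd.read_csv(pos_path, header=0 if "list" not in pos_path.name else None)
    pos.columns = ["barcode", "in_tissue", "array_row", "array_col",
                   "pxl_row_in_fullres", "pxl_col_in_fullres"][: len(pos.columns)]
    pos = pos.set_index(pos["barcode"].astype(str))

    in_tissue = pos.loc[pos["in_tissue"].astype(int) == 1]
    keep = [i for i, b in enumerate(barcodes) if b in set(in_tissue.index)]
    if not keep:
        raise InvalidInputError("no in-tissue spots found")
    kept_barcodes = barcodes.iloc[keep]
    sub = pos.loc[kept_barcodes]
    coords = visium_array_to_xy(
        sub["array_row"].to_numpy(float), sub["array_col"].to_numpy(float)
    )
    gene_names = features.iloc[:, min(1, features.shape[1] - 1)].astype(str).tolist()
    raw = np.asarray(mat[:, keep].todense(), dtype=float)
    matrix = ProfileMatrix.from_raw(raw, gene_names, c=c)
    grid = build_grid(coords, topology="hexagonal")
    return Dataset(matrix=matrix, grid=grid, source=str(d), platform="Visium")


def read_coordinates_table(
    path,
    x_col: str = "x",
    y_col: str = "y",
    sep: str | None = None,
    k: int = 6,
    c: float = DEFAULT_PSEUDOCOUNT,
) -> Dataset:
    """Read a wide table with explicit coordinate columns (unstructured data).

    Rows are locations; all columns other than ``x_col``/``y_col`` are gene
    counts.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    for col in (x_col, y_col):
        if col not in df.columns:
            raise InvalidInputError(f"missing required column {col!r} in {path}")
    coords = df[[x_col, y_col]].to_numpy(dtype=float)
    genes = [str(g) for g in df.columns if g not in (x_col, y_col)]
    if not genes:
        raise InvalidInputError("no gene columns found")
    matrix = ProfileMatrix.from_raw(df[genes].to_numpy(dtype=float).T, genes, c=c)
    grid = build_grid(coords, topology="unstructured", k=k)
    return Dataset(matrix=matrix, grid=grid, source=str(path), platform="unstructured")


def write_results(result, path) -> None:
    """Persist a DiffusionResult (TSV), PatternFamilySet (TSV) or report (JSON)."""
    path = Path(path)
    if isinstance(result, DiffusionResult):
        df = result_table(result)
        df.to_csv(path, sep="\t", index=False)
    elif isinstance(result, PatternFamilySet):
        pd.DataFrame(
            {"gene": [str(g) for g in result.selected_genes], "family": result.family_id}
        ).to_csv(path, sep="\t", index=False)
    elif hasattr(result, "to_json"):
        result.to_json(path)
    else:
        raise InvalidInputError(f"cannot serialize object of type {type(result)!r}")


def result_table(result: DiffusionResult) -> pd.DataFrame:
    """DiffusionResult as a tidy per-gene table, ordered by rank then name."""
    df = pd.DataFrame(
        {
            "gene": [str(g) for g in result.gene_names],
            "t_d": result.t_d,
            "t_d_normalized": result.t_d_normalized,
            "rank": result.rank,
            "converged": result.converged,
            "steps": result.steps,
        }
    )
    return df.sort_values(["rank", "gene"], kind="stable").reset_index(drop=True)


def read_results(path) -> pd.DataFrame:
    """Read back a per-gene results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def write_motifs(family_set: PatternFamilySet, grid: CaptureGrid, path) -> None:
    """Write family motifs as a location-value TSV (x, y, motif_1..motif_k)."""
    data = {"x": grid.coords[:, 0], "y": grid.coords[:, 1]}
    for f in range(1, family_set.n_families + 1):
        data[f"motif_{f}"] = family_set.motifs[f - 1]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
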