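"""Count normalization and gene filtering.

Raw transcript counts ``y_g`` are turned into the diffusion initial
condition ``u_g`` by a log2 transform with pseudocount ``c`` followed by
division with the per-gene maximum:

    y_hat = log2(y + c),   u = y_hat / max(y_hat)

The default pseudocount is 2 rather than the common 1: sparse profiles
(few non-zero observations surrounded by zeros) otherwise create
artificially steep gradients that inflate their diffusion time.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

DEFAULT_PSEUDOCOUNT = 2.0
#: Name patterns removed by default: mitochondrial and ribosomal genes.
DEFAULT_NAME_PATTERNS = (r"^[Mm][Tt]-", r"^R[pP][SsLl]")


def normalize_profiles(raw: np.ndarray, c: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Normalize a genes x locations count matrix to the unit interval.

    Per gene: ``u = log2(y + c) / max(log2(y + c))``.  With ``c > 1`` the
    transformed values are strictly positive, so ``u`` lies in ``(0, 1]``
    and attains 1 at the gene's maximum.  An all-zero gene with ``c = 1``
    has ``max = 0``; such genes are set to all-zero and a warning is
    raised — they must be excluded before diffusion.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise InvalidInputError("raw counts must be non-negative")
    if not c > 0:
        raise InvalidParameterError("pseudocount c must be positive")
    y_hat = np.log2(raw + c)
    maxes = y_hat.max(axis=-1, keepdims=True)
    degenerate = (maxes <= 0).ravel()
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) have max(log2(y+c)) <= 0 "
            "(all-zero counts with c <= 1); their normalized profile is set "
            "to zero and they must be filtered out before diffusion",
            stacklevel=2,
        )
        maxes = np.where(maxes <= 0, 1.0, maxes)
        u = y_hat / maxes
        u[degenerate] = 0.0
        return u
    return y_hat / maxes


@dataclass
class ProfileMatrix:
    """Genes x locations counts plus the normalized diffusion field.

    ``raw`` holds the observed counts ``y_g``; ``normalized`` the field
    ``u_g`` in [0, 1] used to initialize the diffusion simulation.
    """

    gene_names: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if len(self.gene_names) != len(set(self.gene_names)):
            raise InvalidInputError("gene names must be unique")
        if self.raw.shape != self.normalized.shape:
            raise InvalidInputError("raw and normalized shapes differ")
        if self.raw.shape[0] != len(self.gene_names):
            raise InvalidInputError("gene_names length does not match matrix rows")
        if self.degenerate is None:
            self.degenerate = ~self.normalized.any(axis=1)

    @classmethod
    def from_raw(
        cls,
        raw: np.ndarray,
        gene_names=None,
        c: float = DEFAULT_PSEUDOCOUNT,
    ) -> "ProfileMatrix":
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        if gene_names is None:
            gene_names = [f"gene_{i}" for i in range(raw.shape[0])]
        return cls(
            gene_names=np.asarray(gene_names, dtype=object),
            raw=raw,
            normalized=normalize_profiles(raw, c=c),
            pseudocount=c,
        )

    @property
    def n_genes(self) -> int:
        return self.raw.shape[0]

    @property
    def n_locations(self) -> int:
        return self.raw.shape[1]

    def subset(self, idx) -> "ProfileMatrix":
        """New ProfileMatrix restricted to the given gene indices."""
        idx = np.asarray(idx)
        return ProfileMatrix(
            gene_names=self.gene_names[idx],
            raw=self.raw[idx],
            normalized=self.normalized[idx],
            pseudocount=self.pseudocount,
            degenerate=self.degenerate[idx],
        )


def filter_genes(
    matrix: ProfileMatrix,
    min_locations: int = 10,
    min_total: int = 20,
    name_patterns=DEFAULT_NAME_PATTERNS,
) -> ProfileMatrix:
    """Basic quality filter on genes.

    Keeps genes observed (count > 0) in at least ``min_locations``
    locations, with total count at least ``min_total``, whose name matches
    none of ``name_patterns`` (defaults remove mitochondrial ``mt-*`` and
    ribosomal ``Rps*/Rpl*`` genes).
    """
    if min_locations < 0 or min_total < 0:
        raise InvalidParameterError("filter thresholds must be >= 0")
    keep = (matrix.raw > 0).sum(axis=1) >= min_locations
    keep &= matrix.raw.sum(axis=1) >= min_total
    if name_patterns:
        compiled = [re.compile(p) for p in name_patterns]
        name_ok = np.array(
            [not any(p.search(str(g)) for p in compiled) for g in matrix.gene_names]
        )
        keep &= name_ok
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return matrix.subset(np.flatnonzero(keep))
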