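"""Pattern families: group top-ranked profiles by spatial similarity.

The top ``T`` profiles (by diffusion time) are library-size normalized,
decomposed by PCA into *eigenpatterns* — spatial basis patterns over the
capture locations — and projected onto the ``k`` components that explain a
fraction ``p`` of the variance.  The projections are then grouped into
``k`` families by agglomerative clustering with the angle between loading
vectors (cosine distance) as the metric, so that families collect genes
assembled from similar mixtures of eigenpatterns regardless of expression
magnitude.  Each family's representative motif is the combination of
eigenpatterns weighted by its members' mean loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .diffusion import DiffusionResult
from .errors import InvalidInputError, InvalidParameterError
from .preprocessing import ProfileMatrix


@dataclass
class PatternFamilySet:
    """Eigenpattern basis, loadings and family assignments for the top genes."""

    selected_genes: np.ndarray        # T gene names, ranked order
    eigenpatterns: np.ndarray         # k x locations, orthonormal rows
    explained_variance: np.ndarray    # k fractions
    loadings: np.ndarray              # T x k
    family_id: np.ndarray             # T ints in 1..n_families
    motifs: np.ndarray                # n_families x locations

    @property
    def n_families(self) -> int:
        return self.motifs.shape[0]


def library_size_normalize(raw: np.ndarray) -> np.ndarray:
    """Divide each location's counts by that location's total over all genes.

    Zero-total locations are left at zero.
    """
    raw = np.asarray(raw, dtype=float)
    totals = raw.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    return raw / safe


def build_families(
    matrix: ProfileMatrix,
    result: DiffusionResult,
    T: int,
    p: float = 0.8,
    linkage: str = "average",
    n_clusters: int | None = None,
) -> PatternFamilySet:
    """Assort the T top-ranked genes into pattern families.

    Parameters
    ----------
    T
        Number of top genes (by diffusion time) entering the analysis.
    p
        Fraction of variance the retained eigenpatterns must explain;
        ``k`` is the smallest component count reaching it.
    linkage
        Agglomerative linkage (``average`` by default).
    n_clusters
        Number of families; defaults to ``k``.
    """
    if T < 2:
        raise InvalidParameterError("T must be >= 2")
    if not (0 < p <= 1):
        raise InvalidParameterError("p must lie in (0, 1]")
    if T > matrix.n_genes:
        raise InvalidParameterError(f"T={T} exceeds the {matrix.n_genes} available genes")

    # deterministic top-T: by diffusion time descending, ties by name
    order = np.lexsort((result.gene_names, -result.t_d))[:T]
    names = result.gene_names[order]
    pos = {str(g): i for i, g in enumerate(matrix.gene_names)}
    try:
        sel = np.array([pos[str(g)] for g in names])
    except KeyError as e:
        raise InvalidInputError(f"gene {e} ranked but absent from the matrix") from e

    X = library_size_normalize(matrix.raw)[sel]
    if not X.any():
        raise InvalidInputError("selected submatrix is all zero")

    # center each gene's profile over locations: within a family, genes
    # whose patterns are proportional then project to proportional loading
    # vectors, which is what makes the angle metric meaningful
    centered = X - X.mean(axis=1, keepdims=True)
    total_var = float((centered ** 2).sum())
    if total_var <= 1e-30:
        # spatially constant profiles: a single family containing everything
        motif = X.mean(axis=0, keepdims=True)
        e0 = motif / max(np.linalg.norm(motif), 1e-30)
        return PatternFamilySet(
            selected_genes=names.copy(),
            eigenpatterns=e0,
            explained_variance=np.ones(1),
            loadings=np.zeros((T, 1)),
            family_id=np.ones(T, dtype=int),
            motifs=motif,
        )

    # uncentered PCA (plain SVD) so proportionality is preserved exactly
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    evr_all = svals ** 2 / (svals ** 2).sum()
    k = int(np.searchsorted(np.cumsum(evr_all), p) + 1)
    k = min(k, len(evr_all))

    eigenpatterns = vt[:k]
    loadings = centered @ eigenpatterns.T
    evr = evr_all[:k]
    n_fam = n_clusters if n_clusters is not None else k

    if n_fam <= 1:
        labels = np.zeros(T, dtype=int)
    elif n_fam >= T:
        labels = np.arange(T)
    else:
        norms = np.linalg.norm(loadings, axis=1)
        if np.any(norms == 0):
            warnings.warn(
                "zero loading vector(s); cosine distance undefined, jittering "
                "to the first eigenpattern direction",
                stacklevel=2,
            )
            loadings = loadings.copy()
            loadings[norms == 0, 0] = 1e-12
        model = AgglomerativeClustering(
            n_clusters=n_fam, metric="cosine", linkage=linkage
        )
        labels = model.fit_predict(loadings)

    # relabel families 1..k by first occurrence in ranked gene order
    remap: dict[int, int] = {}
    family_id = np.empty(T, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        family_id[i] = remap[lab]
    n_fam = len(remap)

    motifs = np.vstack([
        _motif(loadings, eigenpatterns, family_id == f) for f in range(1, n_fam + 1)
    ])
    return PatternFamilySet(
        selected_genes=names.copy(),
        eigenpatterns=eigenpatterns,
        explained_variance=evr,
        loadings=loadings,
        family_id=family_id,
        motifs=motifs,
    )


def _motif(loadings: np.ndarray, eigenpatterns: np.ndarray, members: np.ndarray) -> np.ndarray:
    if not members.any():
        return np.zeros(eigenpatterns.shape[1])
    return loadings[members].mean(axis=0) @ eigenpatterns


def motif_field(family_set: PatternFamilySet, family: int) -> np.ndarray:
    """Representative spatial motif of one family.

    The linear combination of eigenpatterns weighted by the mean loadings
    of the family's members.  An empty family yields a zero field with a
    warning.
    """
    if not 1 <= family <= family_set.n_families:
        raise InvalidParameterError(
            f"family must be in 1..{family_set.n_families}; got {family}"
        )
    members = family_set.family_id == family
    if not members.any():
        warnings.warn(f"family {family} has no members; zero motif", stacklevel=2)
        return np.zeros(family_set.eigenpatterns.shape[1])
    return _motif(family_set.loadings, family_set.eigenpatterns, members)
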