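"""Community structure of annual diet composition.

Years are compared by the Bray-Curtis dissimilarity of their prey
frequency-of-occurrence profiles, grouped by Ward hierarchical clustering
(the ward.D2 variant: raw dissimilarities in, squared inside the
Lance-Williams update) and embedded by non-metric multidimensional scaling
(nMDS), with prey taxa placed at occurrence-weighted averages of the year
coordinates.  Bray-Curtis is a bounded semimetric — symmetric, zero on the
diagonal, in [0, 1] — but does not satisfy the triangle inequality, which is
why the non-metric ordination is the appropriate embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform


@dataclass
class DissimilarityMatrix:
    labels: list
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis values must lie in [0, 1]")
        self.values = d

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis(matrix: pd.DataFrame) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities between the rows of a site x species table.

    d(i, j) = sum |x_ik - x_jk| / sum (x_ik + x_jk).  Rows are years, columns
    prey categories (typically FO in percent); entries must be non-negative
    and no row may be all-zero (its composition would be undefined).
    """
    df = pd.DataFrame(matrix)
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("composition matrix must be non-negative")
    zero_rows = np.asarray(x.sum(axis=1) == 0).nonzero()[0]
    if zero_rows.size:
        raise ValueError(
            f"all-zero composition row(s): {list(df.index[zero_rows])}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(list(df.index), d)


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form with leaf labels."""

    linkage: np.ndarray
    labels: list

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict:
        """Leaf label -> cluster id for a k-cluster cut."""
        assignments = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return dict(zip(self.labels, assignments))

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def ward_cluster(D: DissimilarityMatrix) -> Dendrogram:
    """Ward agglomeration on a precomputed dissimilarity matrix.

    Uses the Lance-Williams recursion on squared input dissimilarities
    (the ward.D2 convention — callers pass raw, unsquared values).  Merge
    heights are non-decreasing.
    """
    if len(D.labels) < 2:
        raise ValueError("need at least 2 observations to cluster")
    Z = hierarchy.linkage(D.condensed(), method="ward")
    return Dendrogram(Z, list(D.labels))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # site (year) x dimension, centered
    stress: float              # Kruskal stress-1
    converged: bool
    seed: int | None
    n_iter: int


def _pcoa(d: np.ndarray, k: int) -> np.ndarray:
    """Classical (metric) MDS coordinates: the standard nMDS starting point."""
    n = len(d)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    return v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))


def _degenerate(coords: np.ndarray, d: np.ndarray) -> bool:
    """True when clearly dissimilar sites collapse onto one point.

    Pure stress-1 minimization admits degenerate optima that squeeze whole
    clusters to coincident points (stress near 0, ordination meaningless);
    such solutions must not win the restart competition.
    """
    emb = pdist(coords)
    dis = squareform(d, checks=False)
    apart = dis > 0.5 * np.median(dis)
    if not apart.any():
        return False
    return bool((emb[apart] < 1e-3 * (emb.max() + 1e-12)).any())


def nmds(D: DissimilarityMatrix, k: int = 2, seed: int | None = 0,
         n_restarts: int = 20, max_iter: int = 200) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix into k dimensions.

    Iterative Kruskal stress-1 minimization over monotone-regressed
    dissimilarities, started from the classical (PCoA) solution plus
    ``n_restarts`` random configurations; the lowest-stress non-degenerate
    solution wins and a fixed seed makes the result deterministic.
    Coordinates are mean-centered; only inter-point distances (hence stress)
    are identified — orientation is arbitrary.  Non-convergence is reported
    through ``converged``, not raised.
    """
    from sklearn.manifold import smacof

    n = len(D.labels)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n_sites, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    inits = [_pcoa(D.values, k)]
    inits += [rng.uniform(-0.5, 0.5, size=(n, k)) for _ in range(n_restarts)]
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for init in inits:
            coords, stress, n_iter = smacof(
                D.values, metric=False, n_components=k, init=init, n_init=1,
                max_iter=max_iter, eps=1e-9, normalized_stress=True,
                return_n_iter=True)
            if _degenerate(coords, D.values) and best is not None:
                continue
            if best is None or stress < best[1]:
                best = (coords, stress, n_iter)
    coords, stress, n_iter = best
    coords = coords - coords.mean(axis=0)
    df = pd.DataFrame(coords, index=D.labels,
                      columns=[f"dim{i + 1}" for i in range(k)])
    return OrdinationResult(
        coordinates=df, stress=float(stress),
        converged=bool(n_iter < max_iter), seed=seed, n_iter=int(n_iter),
    )


def species_scores(coordinates: pd.DataFrame,
                   fo_matrix: pd.DataFrame) -> pd.DataFrame:
    """Place each taxon at the occurrence-weighted average of site coordinates.

    ``fo_matrix`` is the same site x taxon table the ordination was built
    from; a taxon's score is sum_y w_y coords_y / sum_y w_y with w_y its FO in
    year y.  Taxa never observed are omitted with a warning.
    """
    fo = fo_matrix.loc[coordinates.index]
    scores = {}
    for taxon in fo.columns:
        w = fo[taxon].to_numpy(dtype=float)
        total = w.sum()
        if total <= 0:
            warnings.warn(f"taxon {taxon!r} has zero total occurrence; omitted",
                          stacklevel=2)
            continue
        scores[taxon] = (coordinates.to_numpy() * w[:, None]).sum(0) / total
    return pd.DataFrame.from_dict(scores, orient="index",
                                  columns=coordinates.columns)
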