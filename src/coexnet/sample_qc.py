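"""Sample-level quality control: Jaccard outlier detection and leading-logFC MDS.

Outlier replicates are detected per treatment group by hierarchically
clustering samples on the quantitative Jaccard (Ružička) distance

    d(x, y) = 1 - sum_g min(x_g, y_g) / sum_g max(x_g, y_g)

over cpm profiles, cutting the dendrogram at a fixed height (default 0.4) and
flagging every sample outside the largest cluster.  The quantitative form is
algebraically identical to 2B/(1+B) with B the Bray–Curtis dissimilarity.

Group separation is visualised by classical multidimensional scaling of the
"leading log-fold-change" distance: for each sample pair, the root mean
square of the largest ``top_genes`` absolute log2 cpm differences (a prior
count is added before taking logs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import NormalizedMatrix

__all__ = [
    "SampleDistanceMatrix",
    "Dendrogram",
    "MDSResult",
    "jaccard_distance",
    "sample_distances",
    "cluster_samples",
    "flag_outliers",
    "dendrogram_to_newick",
    "leading_logfc_distances",
    "classical_mds",
    "leading_logfc_mds",
]


def jaccard_distance(x, y, binary: bool = False) -> float:
    """Quantitative Jaccard (Ružička) distance between two abundance vectors.

    With ``binary=True`` vectors are reduced to presence/absence first, giving
    the classical set-based Jaccard distance.  Raises if both vectors are
    identically zero (the distance is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundance vectors must be non-negative")
    if binary:
        x = (x > 0).astype(float)
        y = (y > 0).astype(float)
    denom = np.maximum(x, y).sum()
    if denom == 0:
        raise ValueError("Jaccard distance undefined for two all-zero vectors")
    return float(1.0 - np.minimum(x, y).sum() / denom)


@dataclass(frozen=True)
class SampleDistanceMatrix:
    """Symmetric sample × sample distance matrix with zero diagonal."""

    sample_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = self.d
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


def sample_distances(
    nm: NormalizedMatrix | pd.DataFrame,
    binary: bool = False,
) -> SampleDistanceMatrix:
    """Pairwise Jaccard distances between the samples (columns) of a cpm matrix."""
    values = nm.cpm if isinstance(nm, NormalizedMatrix) else nm
    ids = tuple(str(s) for s in values.columns)
    X = values.to_numpy(dtype=float).T  # samples × genes
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(X[i], X[j], binary=binary)
    return SampleDistanceMatrix(ids, d)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result: scipy linkage matrix + leaf labels."""

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    method: str = "complete"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def cluster_samples(
    dm: SampleDistanceMatrix,
    linkage: str = "complete",
) -> Dendrogram:
    """Hierarchically cluster samples from a distance matrix.

    ``linkage`` is ``"complete"`` (default) or ``"average"``.  Merge heights
    are non-decreasing for both (they are monotone linkages).
    """
    if linkage not in {"complete", "average"}:
        raise ValueError(f"unsupported linkage: {linkage!r}")
    if len(dm.sample_ids) < 2:
        raise ValueError("need at least two samples to cluster")
    if np.any(~np.isfinite(dm.d)):
        raise ValueError("non-finite distances")
    Z = hierarchy.linkage(squareform(dm.d, checks=False), method=linkage)
    return Dendrogram(Z, dm.sample_ids, linkage)


def flag_outliers(dend: Dendrogram, cut_height: float = 0.4) -> set[str]:
    """Cut the dendrogram and flag samples outside the largest cluster.

    Clusters are formed at ``cut_height`` (samples merge while their linkage
    height is <= the cut); every sample not in the biggest resulting cluster
    is flagged.  An empty set means all samples co-cluster below the cut.
    A tie for the largest cluster is ambiguous and raises.
    """
    if cut_height <= 0:
        raise ValueError("cut_height must be > 0")
    assignments = hierarchy.fcluster(dend.linkage_matrix, t=cut_height,
                                     criterion="distance")
    ids, sizes = np.unique(assignments, return_counts=True)
    if len(ids) == 1:
        return set()
    biggest = sizes.max()
    if (sizes == biggest).sum() > 1:
        raise ValueError(
            "tie for the largest cluster at the cut height; "
            "inspect the dendrogram manually"
        )
    keep = ids[np.argmax(sizes)]
    return {lab for lab, a in zip(dend.labels, assignments) if a != keep}


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Serialise the dendrogram as a Newick string (branch lengths = height gaps)."""
    tree = hierarchy.to_tree(dend.linkage_matrix)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{dend.labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


@dataclass(frozen=True)
class MDSResult:
    """Two-dimensional classical MDS embedding of samples."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # (n_samples, 2)
    eigenvalues: np.ndarray
    distance_used: str = "leading-logFC"


def leading_logfc_distances(
    nm: NormalizedMatrix | pd.DataFrame,
    top_genes: int = 500,
    prior: float = 2.0,
) -> SampleDistanceMatrix:
    """Leading log-fold-change distance between every sample pair.

    For samples i, j the distance is the root mean square of the
    ``top_genes`` largest values of |log2(cpm_gi + prior) - log2(cpm_gj + prior)|
    over genes — i.e. the pair-specific genes that separate the two samples
    most drive their distance.
    """
    values = nm.cpm if isinstance(nm, NormalizedMatrix) else nm
    if top_genes < 1:
        raise ValueError("top_genes must be >= 1")
    ids = tuple(str(s) for s in values.columns)
    L = np.log2(values.to_numpy(dtype=float) + prior)  # genes × samples
    n_genes, n = L.shape
    k = top_genes
    if n_genes < top_genes:
        warnings.warn(
            f"only {n_genes} genes available; using all for the leading-logFC "
            f"distance (requested top {top_genes})",
            stacklevel=2,
        )
        k = n_genes
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diffs = np.abs(L[:, i] - L[:, j])
            if k < n_genes:
                top = np.partition(diffs, n_genes - k)[n_genes - k:]
            else:
                top = diffs
            d[i, j] = d[j, i] = float(np.sqrt(np.mean(top ** 2)))
    return SampleDistanceMatrix(ids, d)


def classical_mds(dm: SampleDistanceMatrix, n_dims: int = 2) -> MDSResult:
    """Classical (Torgerson) metric MDS: double-centering + eigendecomposition.

    Coordinates along each axis are centred at zero; axes are ordered by
    decreasing eigenvalue and sign-fixed so the largest-magnitude loading is
    positive (embeddings are otherwise only defined up to reflection).
    """
    D2 = dm.d ** 2
    n = D2.shape[0]
    if n < 3:
        raise ValueError("classical MDS needs at least 3 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, n_dims))
    for a in range(min(n_dims, n)):
        lam = max(eigval[a], 0.0)
        axis = eigvec[:, a] * np.sqrt(lam)
        if np.abs(axis).max() > 0 and axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        coords[:, a] = axis
    coords -= coords.mean(axis=0, keepdims=True)
    return MDSResult(dm.sample_ids, coords, eigval[:n_dims], "euclidean")


def leading_logfc_mds(
    nm: NormalizedMatrix | pd.DataFrame,
    top_genes: int = 500,
    prior: float = 2.0,
) -> MDSResult:
    """Embed samples in 2-D by classical MDS of the leading-logFC distance."""
    dm = leading_logfc_distances(nm, top_genes=top_genes, prior=prior)
    res = classical_mds(dm)
    return MDSResult(res.sample_ids, res.coordinates, res.eigenvalues,
                     "leading-logFC")
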