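"""Expression analytics: correlation, hierarchical clustering, PCA, MDS.

These operate on any :class:`~seqlens.quantify.ExpressionTable` (the
recommended input scale is log2 normalized counts with pseudocount 1).
Correlation can be gene-wise (between genes, across samples) or sample-wise
(between samples, across genes). Clustering is standard agglomerative
linkage; PCA treats samples as observations over gene dimensions (the
sample-QC orientation); MDS is the classical principal-coordinates method
(double-centering plus eigendecomposition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .quantify import ExpressionTable

logger = logging.getLogger(__name__)

DISTANCES = ("euclidean", "manhattan", "one_minus_corr")
LINKAGES = ("single", "complete", "average", "ward")
CORR_METHODS = ("pearson", "spearman", "kendall")


class AnalyticsError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    axis: str  # {gene, sample}
    method: str
    labels: list[str]
    matrix: np.ndarray  # symmetric, unit diagonal; NaN for constant vectors
    row_order: list[int]  # dendrogram leaf order

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _expr_frame(expr: ExpressionTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(expr, ExpressionTable):
        return expr.to_dataframe()
    return expr


def correlation_matrix(
    expr: ExpressionTable | pd.DataFrame,
    axis: str = "sample",
    method: str = "pearson",
) -> CorrelationResult:
    """Pairwise correlations between genes (across samples) or samples
    (across genes). Kendall is the tie-corrected tau-b. Constant vectors
    yield undefined (NaN) entries, reported and logged, with a unit
    diagonal kept for non-constant vectors."""
    if method not in CORR_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if axis not in ("gene", "sample"):
        raise ValueError("axis must be 'gene' or 'sample'")
    df = _expr_frame(expr)
    vectors = df.T if axis == "gene" else df  # columns = items to correlate
    if vectors.shape[1] < 2:
        raise AnalyticsError("correlation needs >= 2 vectors")
    if vectors.shape[0] < 3:
        raise AnalyticsError("correlation needs vectors of length >= 3")
    mat = vectors.corr(method=method).to_numpy()
    constant = vectors.std(axis=0).to_numpy() == 0
    if np.any(constant):
        logger.warning(
            "%d constant vector(s): correlation undefined (NaN)",
            int(constant.sum()),
        )
        mat[constant, :] = np.nan
        mat[:, constant] = np.nan
    np.fill_diagonal(mat, np.where(constant, np.nan, 1.0))

    finite = mat.copy()
    finite[~np.isfinite(finite)] = 0.0
    np.fill_diagonal(finite, 1.0)
    if mat.shape[0] > 2:
        dist = squareform(1.0 - finite, checks=False)
        order = hierarchy.leaves_list(hierarchy.linkage(dist, "average"))
    else:
        order = np.arange(mat.shape[0])
    return CorrelationResult(
        axis=axis,
        method=method,
        labels=list(vectors.columns),
        matrix=mat,
        row_order=list(map(int, order)),
    )


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge history (scipy linkage matrix) plus leaf order."""

    linkage_matrix: np.ndarray
    labels: list[str]
    distance: str
    linkage: str

    @property
    def leaf_order(self) -> list[int]:
        return list(map(int, hierarchy.leaves_list(self.linkage_matrix)))

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return render(tree, tree.dist).rsplit(":", 1)[0] + ";"


def _distance_matrix(data: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return pdist(data, "euclidean")
    if distance == "manhattan":
        return pdist(data, "cityblock")
    if distance == "one_minus_corr":
        corr = np.corrcoef(data)
        return squareform(1.0 - corr, checks=False)
    raise ValueError(f"unknown distance {distance!r}; choose from {DISTANCES}")


def hierarchical_cluster(
    data: np.ndarray | pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "average",
    precomputed: bool = False,
    labels: list[str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering of the rows of ``data`` (or of a precomputed
    square distance matrix). Ward linkage demands euclidean distances and is
    rejected otherwise; leaf order is deterministic, ties broken by input
    index (scipy convention)."""
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    if isinstance(data, pd.DataFrame):
        labels = labels or [str(i) for i in data.index]
        data = data.to_numpy()
    data = np.asarray(data, dtype=float)
    if precomputed:
        if data.shape[0] != data.shape[1]:
            raise AnalyticsError("precomputed distances must be square")
        if linkage == "ward":
            raise AnalyticsError(
                "ward linkage requires euclidean distances computed from "
                "coordinates, not a precomputed matrix"
            )
        condensed = squareform(data, checks=False)
        n = data.shape[0]
    else:
        if data.shape[0] < 2:
            raise AnalyticsError("clustering needs >= 2 items")
        if linkage == "ward" and distance != "euclidean":
            raise AnalyticsError("ward linkage requires euclidean distance")
        condensed = _distance_matrix(data, distance)
        n = data.shape[0]
    if not np.all(np.isfinite(condensed)):
        raise AnalyticsError("non-finite distances")
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(
        linkage_matrix=Z,
        labels=labels or [str(i) for i in range(n)],
        distance=distance,
        linkage=linkage,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray  # samples x k
    loadings: np.ndarray  # features x k
    explained: np.ndarray  # fraction per component, sums to 1
    centered: bool
    scaled: bool
    sample_ids: list[str]
    feature_ids: list[str]

    def biplot_data(self) -> tuple[np.ndarray, np.ndarray]:
        """Scores plus loadings scaled into the score frame, for a biplot."""
        span = np.abs(self.scores).max(axis=0)
        lmax = np.abs(self.loadings).max(axis=0)
        lmax[lmax == 0] = 1.0
        return self.scores, self.loadings * (span / lmax)


def pca(
    expr: ExpressionTable | pd.DataFrame | np.ndarray,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """PCA with samples as observations over feature dimensions.

    Computed by SVD of the (optionally centered/standardized) samples x
    features matrix. Zero-variance features are dropped (with a warning)
    when scaling. Gene-axis PCA is obtained by transposing the input
    explicitly.
    """
    if isinstance(expr, ExpressionTable):
        df = expr.to_dataframe().T  # samples x features
    elif isinstance(expr, pd.DataFrame):
        df = expr
    else:
        df = pd.DataFrame(np.asarray(expr, dtype=float))
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise AnalyticsError("pca needs >= 2 samples and >= 2 features")
    feature_ids = [str(c) for c in df.columns]
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not np.all(keep):
            logger.warning(
                "dropping %d zero-variance feature(s) for scaled PCA",
                int((~keep).sum()),
            )
            X = X[:, keep]
            feature_ids = [f for f, k in zip(feature_ids, keep) if k]
            sd = sd[keep]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # fix component signs for reproducibility: largest |loading| positive
    signs = np.sign(Vt[np.arange(len(s)), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    return PcaResult(
        scores=U * s,
        loadings=Vt.T,
        explained=explained,
        centered=center,
        scaled=scale,
        sample_ids=[str(i) for i in df.index],
        feature_ids=feature_ids,
    )


# ---------------------------------------------------------------------------
# classical MDS (principal coordinates)
# ---------------------------------------------------------------------------

@dataclass
class MdsResult:
    coordinates: np.ndarray  # points x k
    eigenvalues: np.ndarray  # non-increasing


def mds(distances: np.ndarray, k: int = 2) -> MdsResult:
    """Classical multidimensional scaling (principal coordinates).

    Double-centers the squared distance matrix and eigendecomposes it;
    coordinates are eigenvectors scaled by sqrt(eigenvalue). Dimensions with
    negative eigenvalues (non-euclidean input) are truncated with a warning.
    Exact for euclidean distances with full ``k``.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise AnalyticsError("distance matrix must be square")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise AnalyticsError("distance matrix is not symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise AnalyticsError("distance matrix must have a zero diagonal")
    if not (1 <= k < n):
        raise AnalyticsError("require 1 <= k < number of points")
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if np.any(eigvals[:k] < -1e-9 * max(1.0, abs(eigvals[0]))):
        logger.warning(
            "negative eigenvalues in classical MDS (non-euclidean input); "
            "truncating"
        )
    lam = np.clip(eigvals[:k], 0.0, None)
    coords = eigvecs[:, :k] * np.sqrt(lam)[None, :]
    return MdsResult(coordinates=coords, eigenvalues=eigvals)


def procrustes_residual(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum sum of squared distances between configurations after
    translation, rotation/reflection, and uniform scaling of ``b``."""
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(a, b)
    return float(disparity)
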