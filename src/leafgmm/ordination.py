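"""Ordination and screening of Procrustes shape coordinates: PCA,
outlier detection, and UPGMA phenograms with cophenetic correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from leafgmm.superimpose import AlignedShapes

_RANK_TOL = 1e-12


@dataclass
class ShapePCA:
    """Eigendecomposition of the shape-coordinate covariance matrix.

    A 2D Procrustes alignment of k landmarks leaves 2k - 4 shape
    dimensions, so at most ``min(n - 1, 2k - 4)`` eigenvalues are
    nonzero; the remainder are reported as exact zeros.
    """

    eigenvalues: np.ndarray  # descending, zeros beyond numerical rank
    eigenvectors: np.ndarray  # (2k, m), orthonormal columns
    scores: np.ndarray  # (n, m), mean-centered projections
    pct_variance: np.ndarray

    @property
    def n_nonzero(self) -> int:
        return int((self.eigenvalues > 0).sum())


def shape_pca(aligned: AlignedShapes | np.ndarray) -> ShapePCA:
    """PCA of tangent-space shape coordinates.

    The decomposition is of the (n-1)-denominator covariance matrix;
    scores are centered projections, so pairwise score distances equal
    tangent-space shape distances when all components are kept.
    Eigenvector signs are fixed by making each column's
    largest-magnitude loading positive.
    """
    x = aligned.shapes if isinstance(aligned, AlignedShapes) else np.asarray(aligned, float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    evals[evals <= _RANK_TOL * max(evals[0], _RANK_TOL)] = 0.0
    # deterministic sign convention
    for j in range(evecs.shape[1]):
        i_max = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = centered @ evecs
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return ShapePCA(eigenvalues=evals, eigenvectors=evecs, scores=scores, pct_variance=pct)


@dataclass
class OutlierReport:
    """Per-specimen distance-to-consensus screening plus per-group
    box-plot summary statistics of centroid size."""

    distances: np.ndarray
    threshold: float
    flagged: np.ndarray  # indices of flagged specimens
    size_stats: dict[str, dict[str, float]]


def _tukey_hinges(values: np.ndarray) -> tuple[float, float, float]:
    """Median and Tukey hinges (medians of the lower/upper halves,
    including the overall median when n is odd)."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    med = float(np.median(v))
    half = (n + 1) // 2
    lower = v[:half]
    upper = v[n - half:]
    return float(np.median(lower)), med, float(np.median(upper))


def outlier_screen(
    aligned: AlignedShapes,
    sizes: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    quantile: float | None = None,
) -> OutlierReport:
    """Flag specimens unusually distant from the consensus shape.

    Under a multivariate-normal model the squared distance to the
    consensus is approximately a scaled chi-square; the effective
    dimensionality is estimated from the eigenvalue spectrum as
    ``(sum lambda)^2 / sum lambda^2`` and a specimen is flagged when its
    squared distance exceeds the ``1 - 1/n`` quantile (configurable via
    ``quantile``) of that fitted distribution.  Also reports box-plot
    statistics (median, Tukey hinges, min, max) of centroid size per
    group.
    """
    x = aligned.shapes
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty alignment")
    centered = x - x.mean(axis=0)
    d2 = (centered**2).sum(axis=1)
    cov_eigs = np.linalg.eigvalsh(centered.T @ centered / (n - 1))
    cov_eigs = np.clip(cov_eigs, 0.0, None)
    total_var = cov_eigs.sum()
    if total_var <= 0:
        threshold = 0.0
        flagged = np.array([], dtype=int)
    else:
        d_eff = total_var**2 / (cov_eigs**2).sum()
        q = 1.0 - 1.0 / n if quantile is None else quantile
        threshold = float((total_var / d_eff) * stats.chi2.ppf(q, d_eff))
        flagged = np.nonzero(d2 > threshold)[0]

    size_stats: dict[str, dict[str, float]] = {}
    if sizes is None:
        sizes = aligned.centroid_sizes
    sizes = np.asarray(sizes, float)
    group_arr = np.asarray(["all"] * n) if groups is None else np.asarray(groups)
    for g in np.unique(group_arr):
        gv = sizes[group_arr == g]
        q1, med, q3 = _tukey_hinges(gv)
        size_stats[str(g)] = {
            "min": float(gv.min()),
            "q1": q1,
            "median": med,
            "q3": q3,
            "max": float(gv.max()),
        }
    return OutlierReport(
        distances=np.sqrt(d2), threshold=np.sqrt(threshold), flagged=flagged, size_stats=size_stats
    )


@dataclass
class PhenogramResult:
    """UPGMA dendrogram of a shape-distance matrix.

    ``linkage_matrix`` is in scipy ``linkage`` form; ``cophenetic_r``
    is the Pearson correlation between the original distances and the
    distances implied by the tree (1 = no distortion).
    """

    linkage_matrix: np.ndarray
    cophenetic_r: float
    cophenetic_distances: np.ndarray  # condensed form
    labels: list[str] | None = None

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)
        labels = self.labels

        def name(idx: int) -> str:
            return labels[idx] if labels is not None else f"s{idx}"

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{name(node.id)}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def upgma_phenogram(
    dist: np.ndarray, labels: list[str] | None = None, linkage: str = "average"
) -> PhenogramResult:
    """Average-linkage (UPGMA) clustering of a symmetric distance matrix
    with its cophenetic correlation.

    Alternative linkages (``single``, ``complete``) can be requested to
    compare distortion across tree-building algorithms.
    """
    dist = np.asarray(dist, float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError(f"distance matrix must be square, got {dist.shape}")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(dist < 0):
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    condensed = squareform(dist, checks=False)
    z = hierarchy.linkage(condensed, method=linkage)
    coph = hierarchy.cophenet(z)
    denom = np.std(condensed) * np.std(coph)
    if denom == 0:
        r = 1.0 if np.allclose(condensed, coph) else 0.0
    else:
        r = float(np.corrcoef(condensed, coph)[0, 1])
    return PhenogramResult(
        linkage_matrix=z, cophenetic_r=r, cophenetic_distances=coph, labels=labels
    )
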