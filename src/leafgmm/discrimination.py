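"""Two-group tests and discriminant analysis on tree-averaged shapes.

After the hierarchical ANOVA has shown tree-level structure, leaves are
averaged within trees to remove pseudoreplication and the populations
are compared with the full battery: t and permutation tests on centroid
size, a dummy-coded regression test, Hotelling's T-squared, Mahalanobis-
and Procrustes-distance permutation tests, Box's M, and a two-group
discriminant analysis with jackknife (leave-one-out) cross-validation.

All multivariate statistics operate on the principal-component subspace
with nonzero eigenvalues, so degrees of freedom are computed on the
true shape dimensionality (2k - 4 for full-rank 2D data) rather than on
the redundant Procrustes coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from leafgmm.superimpose import AlignedShapes

_EIG_TOL = 1e-12


@dataclass
class TreeAveragedDataset:
    """One mean shape vector and one mean centroid size per tree."""

    shapes: np.ndarray  # (T, 2k)
    sizes: np.ndarray  # (T,)
    populations: np.ndarray  # (T,) labels
    trees: np.ndarray  # (T,) labels

    @property
    def n(self) -> int:
        return self.shapes.shape[0]


def average_by_tree(aligned: AlignedShapes, classifiers) -> TreeAveragedDataset:
    """Arithmetic mean of shape coordinates and centroid sizes over all
    observations (leaves x replicas) of each tree."""
    if isinstance(classifiers, pd.DataFrame):
        trees = classifiers["tree"].to_numpy()
        pops = classifiers["population"].to_numpy()
    else:
        trees = np.asarray([c.tree for c in classifiers])
        pops = np.asarray([c.population for c in classifiers])
    if len(trees) != aligned.n:
        raise ValueError("classifier length must match specimen count")
    uniq, inverse = np.unique(trees, return_inverse=True)
    n_tree = uniq.size
    shapes = np.zeros((n_tree, aligned.shapes.shape[1]))
    sizes = np.zeros(n_tree)
    counts = np.bincount(inverse, minlength=n_tree).astype(float)
    np.add.at(shapes, inverse, aligned.shapes)
    np.add.at(sizes, inverse, aligned.centroid_sizes)
    shapes /= counts[:, None]
    sizes /= counts
    tree_pop = np.empty(n_tree, dtype=object)
    tree_pop[inverse] = pops
    return TreeAveragedDataset(shapes=shapes, sizes=sizes, populations=tree_pop.astype(str), trees=uniq)


@dataclass
class TwoSampleResult:
    """Result of a two-group test.

    ``df`` is the degrees-of-freedom pair as conventionally printed
    (``(df,)`` for t, ``(p, n - p - 1)`` for the T-squared F
    approximation).  Permutation P values are
    ``(1 + #{permuted >= observed}) / (B + 1)``.
    """

    statistic: float
    df: tuple
    p_parametric: float | None = None
    p_permutation: float | None = None
    n_permutations: int = 0
    mahalanobis_d: float | None = None
    procrustes_d: float | None = None
    extra: dict = field(default_factory=dict)


def _split_two(values: np.ndarray, groups: np.ndarray):
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"exactly two groups required, got {levels.size}")
    mask = groups == levels[0]
    return values[mask], values[~mask], levels


def pc_subspace(shapes: np.ndarray, tol: float = _EIG_TOL) -> np.ndarray:
    """Project shapes onto the centered PC subspace with eigenvalues
    above ``tol`` times the largest, dropping the degenerate dimensions
    a Procrustes alignment leaves behind."""
    x = np.asarray(shapes, float)
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / max(x.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > tol * max(evals[0], tol)
    return centered @ evecs[:, keep]


def _perm_pvalue(observed: float, permuted: np.ndarray) -> float:
    b = permuted.size
    return float((1 + (permuted >= observed - 1e-12).sum()) / (b + 1))


def size_t_test(
    sizes: np.ndarray, groups: np.ndarray, n_perm: int = 10000, seed: int | None = None
) -> TwoSampleResult:
    """Pooled-variance two-sample t test with a permutation companion
    (two-sided, on |t|)."""
    a, b, _ = _split_two(np.asarray(sizes, float), groups)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")

    def tstat(u, v):
        sp2 = ((u.size - 1) * u.var(ddof=1) + (v.size - 1) * v.var(ddof=1)) / (u.size + v.size - 2)
        if sp2 <= 0:
            raise ValueError("zero pooled variance")
        return (u.mean() - v.mean()) / np.sqrt(sp2 * (1 / u.size + 1 / v.size))

    t_obs = float(tstat(a, b))
    df = n1 + n2 - 2
    p_par = float(2 * stats.t.sf(abs(t_obs), df))
    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        perm = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.permutation(pooled.size)
            perm[i] = abs(tstat(pooled[idx[:n1]], pooled[idx[n1:]]))
        p_perm = _perm_pvalue(abs(t_obs), perm)
    return TwoSampleResult(
        statistic=t_obs, df=(df,), p_parametric=p_par, p_permutation=p_perm, n_permutations=n_perm
    )


def dummy_regression_test(
    response: np.ndarray, groups: np.ndarray, n_perm: int = 10000, seed: int | None = None
) -> dict:
    """Regress the response on a +/-1 group dummy; report the percent of
    total variance explained with a permutation P value."""
    y = np.asarray(response, float)
    if y.ndim == 1:
        y = y[:, None]
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("dummy regression needs exactly two groups")
    dummy = np.where(groups == levels[0], 1.0, -1.0)

    yc = y - y.mean(axis=0)
    ss_total = float((yc**2).sum())
    if ss_total <= 0:
        raise ValueError("response has zero variance")

    def pct(d):
        dc = d - d.mean()
        beta = (dc @ yc) / (dc @ dc)
        return 100.0 * float(((np.outer(dc, beta)) ** 2).sum()) / ss_total

    observed = pct(dummy)
    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perm = np.empty(n_perm)
        for i in range(n_perm):
            perm[i] = pct(dummy[rng.permutation(dummy.size)])
        p_perm = _perm_pvalue(observed, perm)
    return {"pct_variance": observed, "p_permutation": p_perm, "n_permutations": n_perm}


def _pooled_cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, n2 = a.shape[0], b.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    return (ac.T @ ac + bc.T @ bc) / (n1 + n2 - 2)


def hotelling_t2(shapes: np.ndarray, groups: np.ndarray, reduce: bool = True) -> TwoSampleResult:
    """Hotelling's T-squared for two groups, with the exact F
    approximation ``F = (n - p - 1) / ((n - 2) p) * T^2`` on df
    ``(p, n - p - 1)``."""
    x = pc_subspace(shapes) if reduce else np.asarray(shapes, float)
    a, b, _ = _split_two(x, groups)
    n1, n2, p = a.shape[0], b.shape[0], x.shape[1]
    if n1 + n2 - 2 <= p - 1 or p >= n1 + n2 - 1:
        raise ValueError(f"singular case: p = {p} too large for n = {n1 + n2}")
    diff = a.mean(axis=0) - b.mean(axis=0)
    sp = _pooled_cov(a, b)
    d2 = float(diff @ np.linalg.solve(sp, diff))
    t2 = (n1 * n2) / (n1 + n2) * d2
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    p_par = float(stats.f.sf(f_stat, p, df2))
    return TwoSampleResult(
        statistic=float(t2),
        df=(p, df2),
        p_parametric=p_par,
        mahalanobis_d=float(np.sqrt(d2)),
        extra={"F": float(f_stat)},
    )


def distance_permutation_test(
    shapes: np.ndarray,
    groups: np.ndarray,
    metric: str = "procrustes",
    n_perm: int = 10000,
    seed: int | None = None,
) -> TwoSampleResult:
    """Permutation test on the between-group mean distance.

    ``procrustes``: Euclidean norm of the mean-shape difference in
    tangent space.  ``mahalanobis``: distance through the pooled
    within-group covariance on the nonzero-eigenvalue PC subspace
    (recomputed under every permutation).
    """
    if metric not in ("procrustes", "mahalanobis"):
        raise ValueError(f"unknown metric {metric!r}")
    x = pc_subspace(shapes) if metric == "mahalanobis" else np.asarray(shapes, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("exactly two groups required")
    mask = groups == levels[0]
    n1 = int(mask.sum())

    def dist(m):
        a, b = x[m], x[~m]
        diff = a.mean(axis=0) - b.mean(axis=0)
        if metric == "procrustes":
            return float(np.linalg.norm(diff))
        sp = _pooled_cov(a, b)
        try:
            return float(np.sqrt(diff @ np.linalg.solve(sp, diff)))
        except np.linalg.LinAlgError:
            raise ValueError("singular pooled covariance; reduce dimensionality first")

    observed = dist(mask)
    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perm = np.empty(n_perm)
        base = np.zeros(x.shape[0], dtype=bool)
        for i in range(n_perm):
            m = base.copy()
            m[rng.choice(x.shape[0], size=n1, replace=False)] = True
            perm[i] = dist(m)
        p_perm = _perm_pvalue(observed, perm)
    result = TwoSampleResult(
        statistic=observed, df=(), p_permutation=p_perm, n_permutations=n_perm
    )
    if metric == "procrustes":
        result.procrustes_d = observed
    else:
        result.mahalanobis_d = observed
    return result


@dataclass
class DiscriminantResults:
    """Fitted two-group discriminant analysis.

    Confusion tables are row-percentage DataFrames (rows: true group;
    columns: predicted group).  ``scores`` are projections onto the
    discriminant axis, suitable for a histogram display.
    """

    discriminant_vector: np.ndarray
    scores: np.ndarray
    confusion_resub: pd.DataFrame
    confusion_jackknife: pd.DataFrame | None
    group_mean_shapes: dict[str, np.ndarray]
    group_levels: tuple[str, str]
    predicted_resub: np.ndarray
    predicted_jackknife: np.ndarray | None

    @property
    def resub_accuracy(self) -> float:
        return float(np.mean(np.diag(self.confusion_resub.to_numpy())) / 100.0)

    @property
    def jackknife_accuracy(self) -> float:
        if self.confusion_jackknife is None:
            raise ValueError("jackknife cross-validation was not requested")
        return float(np.mean(np.diag(self.confusion_jackknife.to_numpy())) / 100.0)

    def summary(self) -> str:
        lines = ["Two-group discriminant analysis", "=" * 32]
        lines.append("Resubstitution classification (row %):")
        lines.append(self.confusion_resub.round(1).to_string())
        if self.confusion_jackknife is not None:
            lines.append("Jackknife cross-validated classification (row %):")
            lines.append(self.confusion_jackknife.round(1).to_string())
        return "\n".join(lines)


class ShapeDiscriminant:
    """Two-group linear discriminant model on the nonzero-eigenvalue PC
    subspace of the shape coordinates.

    The discriminant vector is ``pooled_cov^-1 (mean1 - mean2)``;
    specimens are classified to the group with the smaller Mahalanobis
    distance (equal priors).  ``fit(cross_validate=True)`` additionally
    produces the jackknife table, refitting means, pooled covariance and
    the rule with each specimen held out.
    """

    def __init__(self, shapes: np.ndarray, groups: np.ndarray, reduce: bool = True):
        self.x = pc_subspace(shapes) if reduce else np.asarray(shapes, float)
        self.groups = np.asarray(groups)
        self.levels = np.unique(self.groups)
        if self.levels.size != 2:
            raise ValueError("discriminant analysis here is two-group only")

    @staticmethod
    def _rule(x, groups, levels):
        a = x[groups == levels[0]]
        b = x[groups == levels[1]]
        sp = _pooled_cov(a, b)
        try:
            sp_inv = np.linalg.inv(sp)
        except np.linalg.LinAlgError:
            raise ValueError("singular pooled covariance; reduce to fewer PCs")
        return a.mean(axis=0), b.mean(axis=0), sp_inv

    @staticmethod
    def _classify(x, m1, m2, sp_inv, levels):
        d1 = np.einsum("ij,jk,ik->i", x - m1, sp_inv, x - m1)
        d2 = np.einsum("ij,jk,ik->i", x - m2, sp_inv, x - m2)
        ties = d1 == d2
        if np.any(ties):
            warnings.warn("classification tie(s) assigned to the first group", stacklevel=2)
        return np.where(d1 <= d2, levels[0], levels[1])

    def fit(self, cross_validate: bool = True) -> DiscriminantResults:
        x, groups, levels = self.x, self.groups, self.levels
        m1, m2, sp_inv = self._rule(x, groups, levels)
        w = sp_inv @ (m1 - m2)
        scores = x @ w
        pred_resub = self._classify(x, m1, m2, sp_inv, levels)

        def confusion(pred):
            table = np.zeros((2, 2))
            for i, g in enumerate(levels):
                mask = groups == g
                for j, h in enumerate(levels):
                    table[i, j] = 100.0 * np.mean(pred[mask] == h)
            return pd.DataFrame(table, index=levels, columns=levels)

        pred_jack = None
        conf_jack = None
        if cross_validate:
            pred_jack = np.empty(x.shape[0], dtype=object)
            for i in range(x.shape[0]):
                keep = np.ones(x.shape[0], dtype=bool)
                keep[i] = False
                m1i, m2i, spi = self._rule(x[keep], groups[keep], levels)
                pred_jack[i] = self._classify(x[i : i + 1], m1i, m2i, spi, levels)[0]
            pred_jack = pred_jack.astype(levels.dtype)
            conf_jack = confusion(pred_jack)

        return DiscriminantResults(
            discriminant_vector=w,
            scores=scores,
            confusion_resub=confusion(pred_resub),
            confusion_jackknife=conf_jack,
            group_mean_shapes={str(levels[0]): m1, str(levels[1]): m2},
            group_levels=(str(levels[0]), str(levels[1])),
            predicted_resub=pred_resub,
            predicted_jackknife=pred_jack,
        )


def discriminant_analysis(
    shapes: np.ndarray, groups: np.ndarray, cross_validate: bool = True
) -> DiscriminantResults:
    """Functional wrapper over :class:`ShapeDiscriminant`."""
    return ShapeDiscriminant(shapes, groups).fit(cross_validate=cross_validate)


def boxs_m(shapes: np.ndarray, groups: np.ndarray) -> dict:
    """Box's M test of covariance-matrix homogeneity with its chi-square
    approximation.

    If any group has too few specimens for a full-rank covariance the
    data are reduced to a smaller PC subspace with a warning.
    """
    x = np.asarray(shapes, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    counts = np.array([(groups == g).sum() for g in levels])
    x = pc_subspace(x)
    p = x.shape[1]
    if counts.min() <= p:
        p_new = int(counts.min() - 1)
        if p_new < 1:
            raise ValueError("a group is too small for any covariance estimate")
        warnings.warn(
            f"group size {counts.min()} <= dimension {p}; reducing to first {p_new} PCs",
            stacklevel=2,
        )
        x = pc_subspace(x)[:, :p_new]
        p = p_new
    g = levels.size
    n = x.shape[0]
    pooled = np.zeros((p, p))
    logdets = []
    for lev, ni in zip(levels, counts):
        xi = x[groups == lev]
        ci = np.cov(xi, rowvar=False)
        pooled += (ni - 1) * ci
        sign, logdet = np.linalg.slogdet(ci)
        if sign <= 0:
            raise ValueError(f"non-positive-definite covariance in group {lev!r}")
        logdets.append(logdet)
    pooled /= n - g
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    m = (n - g) * logdet_pooled - sum((ni - 1) * ld for ni, ld in zip(counts, logdets))
    c = (2 * p**2 + 3 * p - 1) / (6 * (p + 1) * (g - 1)) * (
        sum(1 / (ni - 1) for ni in counts) - 1 / (n - g)
    )
    chi2 = m * (1 - c)
    df = (g - 1) * p * (p + 1) / 2
    return {"M": float(m), "chi2": float(chi2), "chi2_df": float(df), "P": float(stats.chi2.sf(chi2, df))}
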