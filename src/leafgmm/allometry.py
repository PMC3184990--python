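"""Allometry: multivariate regression of shape on size, Pillai-trace
MANCOVA for slopes and intercepts, and pooled within-group
size-correction.

The size-correction fits parallel within-group regressions of shape on
centroid size, predicts every group at a common size (the grand mean by
default), and adds back the residuals, yielding shapes whose
within-group allometric variation has been removed.  Because the lines
are parallel, group mean differences of the corrected shapes do not
depend on the choice of common size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from leafgmm.discrimination import (
    ShapeDiscriminant,
    distance_permutation_test,
    hotelling_t2,
    pc_subspace,
)


@dataclass
class AllometryResults:
    """Multivariate regression of shape coordinates on (log-)size.

    ``slope_vector`` has units of shape change per unit size (per mm, or
    per log-mm when ``use_log``); ``regression_scores`` are projections
    of the centered shapes onto the direction of the slope vector, the
    standard x-axis companion plot of an allometric trend.
    """

    slope_vector: np.ndarray
    intercept: np.ndarray
    pct_variance: float
    p_permutation: float | None
    n_permutations: int
    regression_scores: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    use_log: bool

    def summary(self) -> str:
        lines = ["Multivariate regression of shape on size", "=" * 41]
        lines.append(f"size predictor: {'ln(centroid size)' if self.use_log else 'centroid size'}")
        lines.append(f"% shape variance explained: {self.pct_variance:.3f}")
        if self.p_permutation is not None:
            lines.append(
                f"permutation P: {self.p_permutation:.4f} ({self.n_permutations} permutations)"
            )
        return "\n".join(lines)


class AllometryModel:
    """Shape-on-size regression model (``fit()`` ->
    :class:`AllometryResults`)."""

    def __init__(self, shapes: np.ndarray, sizes: np.ndarray, use_log: bool = False):
        self.shapes = np.asarray(shapes, float)
        sizes = np.asarray(sizes, float)
        if self.shapes.shape[0] != sizes.size:
            raise ValueError("shapes and sizes length mismatch")
        if self.shapes.shape[0] < 3:
            raise ValueError("need at least 3 specimens")
        if use_log:
            if np.any(sizes <= 0):
                raise ValueError("sizes must be positive for a log transform")
            sizes = np.log(sizes)
        if np.ptp(sizes) == 0:
            raise ValueError("sizes are constant; the regression is undefined")
        self.sizes = sizes
        self.use_log = use_log

    def fit(self, n_perm: int = 0, seed: int | None = None) -> AllometryResults:
        y = self.shapes
        s = self.sizes
        yc = y - y.mean(axis=0)
        sc = s - s.mean()
        ss_total = float((yc**2).sum())

        def fit_pct(sv):
            beta = (sv @ yc) / (sv @ sv)
            pred = np.outer(sv, beta)
            return beta, pred, 100.0 * float((pred**2).sum()) / ss_total

        beta, pred, pct = fit_pct(sc)
        intercept = y.mean(axis=0) - beta * s.mean()
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        scores = yc @ direction

        p_perm = None
        if n_perm > 0:
            rng = np.random.default_rng(seed)
            perm = np.empty(n_perm)
            for i in range(n_perm):
                perm[i] = fit_pct(sc[rng.permutation(sc.size)])[2]
            p_perm = float((1 + (perm >= pct - 1e-12).sum()) / (n_perm + 1))

        return AllometryResults(
            slope_vector=beta,
            intercept=intercept,
            pct_variance=pct,
            p_permutation=p_perm,
            n_permutations=n_perm,
            regression_scores=scores,
            fitted=pred + y.mean(axis=0),
            residuals=yc - pred,
            use_log=self.use_log,
        )


def shape_size_regression(
    shapes: np.ndarray,
    sizes: np.ndarray,
    n_perm: int = 0,
    use_log: bool = False,
    seed: int | None = None,
) -> AllometryResults:
    """Functional wrapper over :class:`AllometryModel`."""
    return AllometryModel(shapes, sizes, use_log=use_log).fit(n_perm=n_perm, seed=seed)


def pillai_f(v: float, p: int, df2: int) -> float:
    """F statistic from Pillai's trace for a single-df hypothesis term
    (``s = 1``): ``F = (V / (1 - V)) * (df2 / p)``."""
    if not 0 <= v < 1:
        raise ValueError(f"Pillai's trace must be in [0, 1), got {v}")
    return float(v / (1.0 - v) * df2 / p)


def _residual_cross(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual cross-product matrix of Y on a design, and its rank."""
    q, r = np.linalg.qr(design)
    rank = int((np.abs(np.diag(r)) > 1e-10 * abs(r[0, 0])).sum())
    resid = y - q[:, :rank] @ (q[:, :rank].T @ y)
    return resid.T @ resid, rank


def mancova(shapes: np.ndarray, sizes: np.ndarray, groups: np.ndarray, reduce: bool = True) -> pd.DataFrame:
    """Pillai-trace MANCOVA of shape on group and size.

    Three hypothesis terms are tested, each by comparing a full against
    a reduced model on the nonzero-eigenvalue PC subspace:

    * ``slopes`` — the group x size interaction in
      ``[1, group, size, group x size]`` (parallelism of allometric
      trajectories);
    * ``intercepts`` — the group term in ``[1, group, size]``, after
      the interaction has been dropped;
    * ``size_only`` — the size term in ``[1, size]``.

    Each term has a single hypothesis df, so the exact relation
    ``F = (V / (1 - V)) (df2 / p)`` holds with ``df1 = p`` and
    ``df2 = n - rank(full model) - p + 1``.  The ``pct_explained``
    column is the incremental fit: the drop in residual SS when the
    term enters, as a percent of total shape SS.
    """
    y = pc_subspace(shapes) if reduce else np.asarray(shapes, float)
    sizes = np.asarray(sizes, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("two groups required")
    n, p = y.shape
    g = np.where(groups == levels[0], 1.0, -1.0)
    s = sizes - sizes.mean()
    one = np.ones(n)

    yc = y - y.mean(axis=0)
    ss_total = float((yc**2).sum())

    models = {
        "slopes": (np.column_stack([one, g, s, g * s]), np.column_stack([one, g, s])),
        "intercepts": (np.column_stack([one, g, s]), np.column_stack([one, s])),
        "size_only": (np.column_stack([one, s]), np.column_stack([one])),
    }
    rows = []
    for term, (full, reduced) in models.items():
        e_full, rank_full = _residual_cross(y, full)
        e_red, _ = _residual_cross(y, reduced)
        h = e_red - e_full
        df2 = n - rank_full - p + 1
        if df2 < 1:
            raise ValueError(f"too few specimens for p = {p} (term {term})")
        v = float(np.trace(h @ np.linalg.inv(h + e_full)))
        v = min(max(v, 0.0), 1.0 - 1e-15)
        f_stat = pillai_f(v, p, df2)
        p_val = float(stats.f.sf(f_stat, p, df2))
        pct = 100.0 * float(np.trace(h)) / ss_total
        rows.append(
            {
                "term": term,
                "pct_explained": pct,
                "pillai_V": v,
                "F": f_stat,
                "df1": p,
                "df2": df2,
                "P": p_val,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SizeCorrectedShapes:
    """Shapes with within-group allometric variation removed."""

    shapes: np.ndarray
    common_size: float
    pooled_slope: np.ndarray
    groups: np.ndarray


def size_correct(
    shapes: np.ndarray,
    sizes: np.ndarray,
    groups: np.ndarray,
    common_size: float | None = None,
    slopes_p: float | None = None,
    force: bool = False,
) -> SizeCorrectedShapes:
    """Pooled within-group size-correction.

    The pooled slope ``B`` is estimated by regressing within-group
    centered shapes on within-group centered sizes (parallel lines);
    corrected shapes are ``shape_i - B (size_i - common_size)``, i.e.
    each group's prediction at the common size plus its residual.

    The correction presumes parallel allometries.  If ``slopes_p`` (the
    MANCOVA slopes-term P value) is below 0.05 the call refuses unless
    ``force=True``.
    """
    y = np.asarray(shapes, float)
    s = np.asarray(sizes, float)
    groups = np.asarray(groups)
    if groups.size != y.shape[0]:
        raise ValueError("groups length mismatch")
    if slopes_p is not None and slopes_p < 0.05 and not force:
        raise ValueError(
            f"slopes test P = {slopes_p:.4g} < 0.05: allometric trajectories are not "
            "parallel; pass force=True to size-correct anyway"
        )
    yw = np.empty_like(y)
    sw = np.empty_like(s)
    for g in np.unique(groups):
        mask = groups == g
        yw[mask] = y[mask] - y[mask].mean(axis=0)
        sw[mask] = s[mask] - s[mask].mean()
    denom = float(sw @ sw)
    if denom == 0:
        raise ValueError("sizes constant within every group")
    b = (sw @ yw) / denom
    s0 = float(s.mean()) if common_size is None else float(common_size)
    corrected = y - np.outer(s - s0, b)
    return SizeCorrectedShapes(shapes=corrected, common_size=s0, pooled_slope=b, groups=groups)


def rerun_group_tests_on_corrected(
    corrected: SizeCorrectedShapes | np.ndarray,
    groups: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict:
    """Re-run the tree-level two-group battery (Hotelling, distance
    permutation tests, jackknifed discriminant analysis) on
    size-corrected shapes."""
    if isinstance(corrected, SizeCorrectedShapes):
        shapes = corrected.shapes
        groups = corrected.groups if groups is None else groups
    else:
        shapes = np.asarray(corrected, float)
        if groups is None:
            raise ValueError("groups required when passing a bare shape matrix")
    return {
        "hotelling": hotelling_t2(shapes, groups),
        "mahalanobis": distance_permutation_test(
            shapes, groups, metric="mahalanobis", n_perm=n_perm, seed=seed
        ),
        "procrustes": distance_permutation_test(
            shapes, groups, metric="procrustes", n_perm=n_perm, seed=seed
        ),
        "discriminant": ShapeDiscriminant(shapes, groups).fit(cross_validate=True),
    }
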