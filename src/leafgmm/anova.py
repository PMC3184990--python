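"""Hierarchical (sequential sum-of-squares) Procrustes ANOVA.

Partitions variation in centroid size (univariate) or tangent-space
shape coordinates (isotropic model: shape SS is the plain sum of the
coordinate-wise univariate SS) across a nested design

    populations > trees > leaves > replicas (measurement error),

with each effect adjusted for all effects earlier in the hierarchy.
The populations effect is tested against trees — the manually corrected
F ratio that makes trees a random effect — trees against leaves, and
leaves against the replica (digitizing) error.

Two degree-of-freedom conventions are offered.  ``morphoj`` replicates
the bookkeeping of the software the protocol was built around:
populations df = P - 1, trees df = T - 1, leaves df = (L - 1) - (P - 1)
- (T - 1), error df = n - L (shape dfs multiply by 2k - 4).  It
double-counts one df between populations and trees; the orthodox
``nested`` convention (trees df = T - P, leaves df = L - T) is the
statistically standard alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EFFECTS = ("populations", "trees", "leaves", "error")


def _classifier_frame(classifiers) -> pd.DataFrame:
    """Coerce classifiers to a DataFrame with population/tree/leaf columns."""
    if isinstance(classifiers, pd.DataFrame):
        df = classifiers
    else:
        df = pd.DataFrame(
            {
                "population": [c.population for c in classifiers],
                "tree": [c.tree for c in classifiers],
                "leaf": [c.leaf for c in classifiers],
            }
        )
    for col in ("population", "tree", "leaf"):
        if col not in df.columns:
            raise ValueError(f"classifiers missing column {col!r}")
        if df[col].isna().any():
            raise ValueError(f"missing classifier value in column {col!r}")
    return df.reset_index(drop=True)


def hierarchical_ss(values: np.ndarray, classifiers) -> dict[str, float]:
    """Sequential nested sums of squares for a (possibly multivariate)
    response.

    The decomposition is by nested group means: population means about
    the grand mean (weighted by counts), tree means about their
    population means, leaf means about their tree means, and
    observations about their leaf means, summed over all response
    columns.  For a purely nested design this equals the sequential
    (type-I) SS from an indicator-variable regression, balanced or not.
    """
    x = np.asarray(values, float)
    if x.ndim == 1:
        x = x[:, None]
    df = _classifier_frame(classifiers)
    if len(df) != x.shape[0]:
        raise ValueError("values and classifiers length mismatch")

    frame = df.copy()
    val_cols = [f"_v{j}" for j in range(x.shape[1])]
    frame[val_cols] = x

    grand = x.mean(axis=0)

    def group_ss(level: str, parent: str | None) -> float:
        means = frame.groupby(level, sort=False)[val_cols].mean()
        counts = frame.groupby(level, sort=False).size()
        if parent is None:
            dev = means.to_numpy() - grand
        else:
            parent_of = frame.groupby(level, sort=False)[parent].first()
            parent_means = frame.groupby(parent, sort=False)[val_cols].mean()
            dev = means.to_numpy() - parent_means.loc[parent_of].to_numpy()
        return float((counts.to_numpy()[:, None] * dev**2).sum())

    ss_pop = group_ss("population", None)
    ss_tree = group_ss("tree", "population")
    ss_leaf = group_ss("leaf", "tree")
    leaf_means = frame.groupby("leaf", sort=False)[val_cols].transform("mean").to_numpy()
    ss_err = float(((x - leaf_means) ** 2).sum())

    leaf_sizes = frame.groupby("leaf", sort=False).size()
    if (leaf_sizes == 1).any():
        warnings.warn(
            "some leaves have a single replica: they contribute zero error df",
            stacklevel=2,
        )
    return {"populations": ss_pop, "trees": ss_tree, "leaves": ss_leaf, "error": ss_err}


def _dfs(n: int, n_pop: int, n_tree: int, n_leaf: int, convention: str) -> dict[str, int]:
    if convention == "morphoj":
        df_pop = n_pop - 1
        df_tree = n_tree - 1
        df_leaf = (n_leaf - 1) - df_pop - df_tree
        df_err = n - n_leaf
    elif convention == "nested":
        df_pop = n_pop - 1
        df_tree = n_tree - n_pop
        df_leaf = n_leaf - n_tree
        df_err = n - n_leaf
    else:
        raise ValueError(f"unknown df convention {convention!r}")
    return {"populations": df_pop, "trees": df_tree, "leaves": df_leaf, "error": df_err}


def f_ratio(ms_num: float, ms_den: float) -> float:
    """Ratio of two mean squares (the manually corrected F when the
    numerator effect is tested against the next random stratum)."""
    if ms_den <= 0:
        raise ValueError("denominator mean square must be positive")
    return float(ms_num / ms_den)


def f_pvalue(f: float, df1: float, df2: float) -> float:
    """Upper-tail probability of F(df1, df2)."""
    if f < 0:
        raise ValueError("F statistic must be non-negative")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.sf(f, df1, df2))


def percent_ss(ss: dict[str, float] | np.ndarray) -> dict[str, float] | np.ndarray:
    """Percent of total sum of squares explained by each effect."""
    if isinstance(ss, dict):
        total = sum(ss.values())
        if total <= 0:
            raise ValueError("total SS must be positive")
        return {k: 100.0 * v / total for k, v in ss.items()}
    arr = np.asarray(ss, float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("total SS must be positive")
    return 100.0 * arr / total


@dataclass
class ProcrustesAnovaResults:
    """Fitted hierarchical ANOVA table.

    ``table`` mirrors the printed layout: effect, explained SS (%), SS,
    MS, df, F, P.  F tests are populations/trees, trees/leaves,
    leaves/error.
    """

    table: pd.DataFrame
    response: str
    df_convention: str
    shape_dims: int
    total_ss: float

    def summary(self) -> str:
        title = f"Hierarchical Procrustes ANOVA — {self.response}"
        lines = [title, "=" * len(title)]
        with pd.option_context("display.float_format", lambda v: f"{v:.6g}"):
            lines.append(self.table.to_string(index=False))
        lines.append(
            f"total SS = {self.total_ss:.6g}   df convention = {self.df_convention}"
            f"   shape dims = {self.shape_dims}"
        )
        return "\n".join(lines)


class ProcrustesAnova:
    """Hierarchical ANOVA model for centroid size or Procrustes shape.

    Parameters
    ----------
    values : array
        Response: centroid sizes ``(n,)`` for ``response="size"`` or
        tangent shape coordinates ``(n, 2k)`` for ``response="shape"``.
    classifiers : sequence of SpecimenClassifiers or DataFrame
        Nested design labels (population / tree / leaf per specimen).
    response : {"size", "shape"}
    df_convention : {"morphoj", "nested"}

    ``fit()`` returns :class:`ProcrustesAnovaResults`.
    """

    def __init__(self, values, classifiers, response: str = "shape", df_convention: str = "morphoj"):
        if response not in ("size", "shape"):
            raise ValueError(f"response must be 'size' or 'shape', got {response!r}")
        self.values = np.asarray(values, float)
        if response == "size" and self.values.ndim != 1:
            self.values = self.values.ravel()
        if response == "shape" and self.values.ndim != 2:
            raise ValueError("shape response needs an (n, 2k) coordinate matrix")
        self.classifiers = _classifier_frame(classifiers)
        self.response = response
        self.df_convention = df_convention

    def fit(self) -> ProcrustesAnovaResults:
        df = self.classifiers
        n = len(df)
        n_pop = df["population"].nunique()
        n_tree = df["tree"].nunique()
        n_leaf = df["leaf"].nunique()
        if n_leaf == n:
            warnings.warn(
                "no replicas present: the measurement-error stratum is empty",
                stacklevel=2,
            )

        shape_dims = 1 if self.response == "size" else self.values.shape[1] - 4
        ss = hierarchical_ss(self.values, df)
        dfs = {k: v * shape_dims for k, v in _dfs(n, n_pop, n_tree, n_leaf, self.df_convention).items()}
        total = sum(ss.values())
        pct = percent_ss(ss) if total > 0 else {k: 0.0 for k in ss}

        rows = []
        have_pops = n_pop >= 2
        effects = [e for e in EFFECTS if have_pops or e != "populations"]
        denom_of = {"populations": "trees", "trees": "leaves", "leaves": "error"}
        ms = {e: (ss[e] / dfs[e] if dfs[e] > 0 else np.nan) for e in EFFECTS}
        for effect in effects:
            f_val = p_val = np.nan
            if effect in denom_of:
                den = denom_of[effect]
                if dfs[effect] > 0 and dfs[den] > 0 and ms[den] > 0:
                    f_val = f_ratio(ms[effect], ms[den])
                    p_val = f_pvalue(f_val, dfs[effect], dfs[den])
            rows.append(
                {
                    "effect": effect,
                    "pct_SS": pct[effect],
                    "SS": ss[effect],
                    "MS": ms[effect],
                    "df": dfs[effect],
                    "F": f_val,
                    "P": p_val,
                }
            )
        table = pd.DataFrame(rows)
        return ProcrustesAnovaResults(
            table=table,
            response=self.response,
            df_convention=self.df_convention,
            shape_dims=shape_dims,
            total_ss=total,
        )


def procrustes_anova(dataset_values, classifiers, response="shape", df_convention="morphoj"):
    """Functional convenience wrapper: build and fit :class:`ProcrustesAnova`."""
    return ProcrustesAnova(dataset_values, classifiers, response, df_convention).fit()
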