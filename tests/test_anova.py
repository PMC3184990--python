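"""Hierarchical sequential-SS ANOVA for size and shape."""

import numpy as np
import pandas as pd
import pytest

import leafgmm as lg
from leafgmm.anova import ProcrustesAnova, f_pvalue, f_ratio, hierarchical_ss, percent_ss
from leafgmm.synthetic import SyntheticSpec, generate_dataset


def unbalanced_design(rng, d=1):
    """Small unbalanced nested design with random responses."""
    rows = []
    for pop, trees in (("A", 3), ("B", 2)):
        for t in range(trees):
            for leaf in range(rng.integers(1, 4)):
                for rep in range(rng.integers(1, 4)):
                    rows.append((pop, f"{pop}t{t}", f"{pop}t{t}l{leaf}"))
    cls = pd.DataFrame(rows, columns=["population", "tree", "leaf"])
    values = rng.normal(size=(len(cls), d))
    return values, cls


def sequential_ss_oracle(values, cls):
    """Sequential SS via residuals of nested indicator regressions."""
    n = len(cls)
    y = np.asarray(values, float)
    if y.ndim == 1:
        y = y[:, None]

    def residual_ss(columns):
        design = [np.ones(n)]
        for col in columns:
            for level in cls[col].unique():
                design.append((cls[col] == level).to_numpy(float))
        x = np.column_stack(design)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return float(((y - x @ beta) ** 2).sum())

    ss_null = residual_ss([])
    ss_pop = residual_ss(["population"])
    ss_tree = residual_ss(["population", "tree"])
    ss_leaf = residual_ss(["population", "tree", "leaf"])
    return {
        "populations": ss_null - ss_pop,
        "trees": ss_pop - ss_tree,
        "leaves": ss_tree - ss_leaf,
        "error": ss_leaf,
    }


class TestHierarchicalSS:
    def test_identical_replicas_give_zero_error(self):
        cls = pd.DataFrame(
            {
                "population": ["A"] * 4 + ["B"] * 4,
                "tree": ["t1", "t1", "t2", "t2", "t3", "t3", "t4", "t4"],
                "leaf": ["l1", "l1", "l2", "l2", "l3", "l3", "l4", "l4"],
            }
        )
        values = np.array([1.0, 1.0, 2.0, 2.0, 5.0, 5.0, 7.0, 7.0])
        assert hierarchical_ss(values, cls)["error"] == 0.0

    def test_constant_data_all_zero(self):
        cls = pd.DataFrame(
            {
                "population": ["A", "A", "B", "B"],
                "tree": ["t1", "t1", "t2", "t2"],
                "leaf": ["l1", "l1", "l2", "l2"],
            }
        )
        ss = hierarchical_ss(np.ones(4), cls)
        assert all(v == 0.0 for v in ss.values())

    @pytest.mark.parametrize("d", [1, 4])
    def test_matches_indicator_regression_oracle_unbalanced(self, rng, d):
        values, cls = unbalanced_design(rng, d=d)
        ours = hierarchical_ss(values, cls)
        oracle = sequential_ss_oracle(values, cls)
        for effect in ours:
            assert ours[effect] == pytest.approx(oracle[effect], abs=1e-9)

    def test_components_sum_to_total(self, rng):
        values, cls = unbalanced_design(rng, d=3)
        ss = hierarchical_ss(values, cls)
        total = float(((values - values.mean(axis=0)) ** 2).sum())
        assert sum(ss.values()) == pytest.approx(total, rel=1e-12)

    def test_isotropic_identity(self, rng):
        """Multivariate shape SS equals the sum of coordinate-wise
        univariate SS."""
        values, cls = unbalanced_design(rng, d=6)
        joint = hierarchical_ss(values, cls)
        columnwise = {k: 0.0 for k in joint}
        for j in range(values.shape[1]):
            for k, v in hierarchical_ss(values[:, j], cls).items():
                columnwise[k] += v
        for effect in joint:
            assert joint[effect] == pytest.approx(columnwise[effect], rel=1e-12)

    def test_balanced_closed_form(self, rng):
        """On a balanced design the sequential SS equal the classical
        nested-ANOVA mean-based formulas."""
        P, T, L, R = 2, 4, 3, 2
        rows, vals = [], []
        for p in range(P):
            for t in range(T):
                for le in range(L):
                    for r in range(R):
                        rows.append((f"p{p}", f"p{p}t{t}", f"p{p}t{t}l{le}"))
                        vals.append(rng.normal())
        cls = pd.DataFrame(rows, columns=["population", "tree", "leaf"])
        y = np.array(vals)
        ss = hierarchical_ss(y, cls)
        grand = y.mean()
        y4 = y.reshape(P, T, L, R)
        pop_m = y4.mean(axis=(1, 2, 3))
        tree_m = y4.mean(axis=(2, 3))
        leaf_m = y4.mean(axis=3)
        assert ss["populations"] == pytest.approx(T * L * R * ((pop_m - grand) ** 2).sum())
        assert ss["trees"] == pytest.approx(L * R * ((tree_m - pop_m[:, None]) ** 2).sum())
        assert ss["leaves"] == pytest.approx(R * ((leaf_m - tree_m[:, :, None]) ** 2).sum())


class TestFStatistics:
    def test_limits(self):
        assert f_pvalue(0.0, 3, 10) == pytest.approx(1.0)
        assert f_pvalue(1e9, 3, 10) < 1e-12

    def test_percent_single_effect(self):
        pct = percent_ss({"populations": 5.0, "trees": 0.0, "leaves": 0.0, "error": 0.0})
        assert pct["populations"] == 100.0

    def test_percent_zero_total_raises(self):
        with pytest.raises(ValueError):
            percent_ss({"populations": 0.0})

    def test_ratio_requires_positive_denominator(self):
        with pytest.raises(ValueError):
            f_ratio(1.0, 0.0)


class TestProcrustesAnovaModel:
    def test_df_conventions_on_study_design(self, aligned, classifier_frame):
        res = ProcrustesAnova(
            aligned.centroid_sizes, classifier_frame, response="size", df_convention="morphoj"
        ).fit()
        assert list(res.table["df"]) == [1, 43, 43, 88]
        res_n = ProcrustesAnova(
            aligned.centroid_sizes, classifier_frame, response="size", df_convention="nested"
        ).fit()
        assert list(res_n.table["df"]) == [1, 42, 44, 88]

    def test_shape_dfs_scale_by_shape_dims(self, aligned, classifier_frame):
        res = ProcrustesAnova(
            aligned.shapes, classifier_frame, response="shape", df_convention="morphoj"
        ).fit()
        assert res.shape_dims == 18
        assert list(res.table["df"]) == [18, 774, 774, 1584]

    def test_table_internal_consistency(self, aligned, classifier_frame):
        res = ProcrustesAnova(aligned.shapes, classifier_frame, response="shape").fit()
        t = res.table
        np.testing.assert_allclose(t["MS"] * t["df"], t["SS"], rtol=1e-10)
        assert t["pct_SS"].sum() == pytest.approx(100.0)
        assert t["SS"].sum() == pytest.approx(res.total_ss, rel=1e-12)
        # F ratios follow the populations/trees, trees/leaves, leaves/error scheme
        ms = t.set_index("effect")["MS"]
        f = t.set_index("effect")["F"]
        assert f["populations"] == pytest.approx(ms["populations"] / ms["trees"])
        assert f["trees"] == pytest.approx(ms["trees"] / ms["leaves"])
        assert f["leaves"] == pytest.approx(ms["leaves"] / ms["error"])

    def test_shape_ss_conserves_gpa_deviations(self, aligned, classifier_frame):
        res = ProcrustesAnova(aligned.shapes, classifier_frame, response="shape").fit()
        centered = aligned.shapes - aligned.shapes.mean(axis=0)
        assert res.total_ss == pytest.approx(float((centered**2).sum()), rel=1e-10)

    def test_zero_digitizing_noise_zeroes_error_stratum(self):
        spec = SyntheticSpec(sigma_error=0.0, sigma_size_error=0.0)
        ds = generate_dataset(spec, seed=3)
        al = lg.gpa(ds)
        cls = pd.DataFrame(
            {
                "population": [c.population for c in ds.classifiers],
                "tree": [c.tree for c in ds.classifiers],
                "leaf": [c.leaf for c in ds.classifiers],
            }
        )
        res = ProcrustesAnova(al.shapes, cls, response="shape").fit()
        err_pct = float(res.table.loc[res.table["effect"] == "error", "pct_SS"].iloc[0])
        assert err_pct < 1e-12

    def test_tree_to_leaf_ms_ratio_tracks_sigma_tree(self):
        """Raising sigma_tree relative to sigma_leaf raises the
        trees:leaves MS ratio."""
        ratios = []
        for sigma_tree in (0.005, 0.03):
            spec = SyntheticSpec(sigma_tree=sigma_tree)
            ratios_i = []
            for seed in range(3):
                ds = generate_dataset(spec, seed=100 + seed)
                al = lg.gpa(ds)
                cls = pd.DataFrame(
                    {
                        "population": [c.population for c in ds.classifiers],
                        "tree": [c.tree for c in ds.classifiers],
                        "leaf": [c.leaf for c in ds.classifiers],
                    }
                )
                t = ProcrustesAnova(al.shapes, cls, response="shape").fit().table
                ms = t.set_index("effect")["MS"]
                ratios_i.append(ms["trees"] / ms["leaves"])
            ratios.append(np.median(ratios_i))
        assert ratios[1] > ratios[0]

    def test_single_population_drops_populations_row(self, rng):
        cls = pd.DataFrame(
            {
                "population": ["A"] * 8,
                "tree": ["t1"] * 4 + ["t2"] * 4,
                "leaf": ["l1", "l1", "l2", "l2", "l3", "l3", "l4", "l4"],
            }
        )
        res = ProcrustesAnova(rng.normal(size=8), cls, response="size").fit()
        assert "populations" not in set(res.table["effect"])
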