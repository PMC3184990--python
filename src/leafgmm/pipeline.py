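"""End-to-end orchestration of the morphometric protocol.

``run_protocol`` executes, in order: read landmarks -> extract
classifiers -> GPA with tangent check -> outlier screen -> PCA and
UPGMA phenogram -> hierarchical Procrustes ANOVA (size and shape) ->
tree averaging -> two-group test battery -> allometry MANCOVA ->
size-correction -> test battery on corrected shapes -> diagram
geometry.  Every numeric table in the bundle records the seed, package
version and df convention used, and the bundle's cross-module
consistency identities (SS conservation, T-squared/Mahalanobis,
Pillai-F) are verified on every run; a failure is fatal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from leafgmm._version import __version__ as _version
from leafgmm.allometry import mancova, pillai_f, rerun_group_tests_on_corrected, shape_size_regression, size_correct
from leafgmm.anova import ProcrustesAnova
from leafgmm.discrimination import (
    ShapeDiscriminant,
    average_by_tree,
    distance_permutation_test,
    dummy_regression_test,
    hotelling_t2,
    size_t_test,
)
from leafgmm.io import LandmarkDataset, read_nts, read_outline, read_tps, parse_classifiers
from leafgmm.ordination import outlier_screen, shape_pca, upgma_phenogram
from leafgmm.superimpose import gpa, tangent_space_check
from leafgmm.warp import lollipops, make_grid, warp_outline, warp_wireframe


@dataclass
class PipelineConfig:
    """Configuration of one protocol run."""

    input_path: str | None = None  # TPS or NTS file; None = synthetic data
    input_format: str = "auto"  # tps | nts | auto
    outline_path: str | None = None
    classifier_ranges: dict[str, tuple[int, int]] | None = None
    fit: str = "partial"
    df_convention: str = "morphoj"
    n_permutations: int = 10000
    seed: int = 42
    use_log_size: bool = False
    common_size: float | None = None
    force_parallel: bool = False
    diagram_kinds: tuple[str, ...] = ("grid", "lollipop")
    magnification: float = 10.0
    output_dir: str | None = None


@dataclass
class ReportBundle:
    """All stage outputs of one protocol run."""

    config: PipelineConfig
    tangent_check: object
    outlier_report: object
    pca: object
    phenogram: object
    anova_size: object
    anova_shape: object
    tree_averaged: object
    size_test: object
    size_dummy: dict
    shape_tests: dict
    discriminant: object
    allometry: object
    mancova_table: pd.DataFrame
    size_corrected: object
    corrected_tests: dict
    diagrams: dict
    metadata: dict = field(default_factory=dict)


def _load(config: PipelineConfig) -> LandmarkDataset:
    if config.input_path is None:
        from leafgmm.synthetic import generate_dataset

        return generate_dataset(seed=config.seed)
    path = Path(config.input_path)
    fmt = config.input_format
    if fmt == "auto":
        fmt = "nts" if path.suffix.lower() in (".nts", ".txt") else "tps"
    configs = read_nts(path) if fmt == "nts" else read_tps(path)
    dataset = LandmarkDataset(configurations=configs)
    dataset = dataset.with_classifiers(config.classifier_ranges or None)
    if config.outline_path:
        dataset.outline = read_outline(config.outline_path)
    return dataset


def _check_identities(bundle: ReportBundle, aligned, classifiers_df) -> None:
    """Fatal cross-module consistency checks."""
    # total shape SS conservation between alignment and ANOVA
    centered = aligned.shapes - aligned.shapes.mean(axis=0)
    total_ss = float((centered**2).sum())
    if not np.isclose(total_ss, bundle.anova_shape.total_ss, rtol=1e-8):
        raise AssertionError("shape SS conservation violated between GPA and ANOVA")
    # Hotelling vs Mahalanobis: T^2 = n1 n2 / n * d^2
    ta = bundle.tree_averaged
    n1 = int((ta.populations == np.unique(ta.populations)[0]).sum())
    n2 = ta.n - n1
    t2 = bundle.shape_tests["hotelling"].statistic
    d = bundle.shape_tests["hotelling"].mahalanobis_d
    if not np.isclose(t2, n1 * n2 / (n1 + n2) * d**2, rtol=1e-8):
        raise AssertionError("T^2 / Mahalanobis identity violated")
    # Pillai-F identity on every MANCOVA row
    for _, row in bundle.mancova_table.iterrows():
        if not np.isclose(row["F"], pillai_f(row["pillai_V"], int(row["df1"]), int(row["df2"])), rtol=1e-8):
            raise AssertionError("Pillai-F identity violated")


def run_protocol(config: PipelineConfig | None = None) -> ReportBundle:
    """Run the complete protocol and return the report bundle.

    With ``config.output_dir`` set, each stage's tables are also written
    as delimited text under that directory.
    """
    config = config or PipelineConfig()
    dataset = _load(config)
    if dataset.classifiers is None:
        raise ValueError("dataset has no classifiers; provide classifier_ranges")
    cls_df = pd.DataFrame(
        {
            "population": [c.population for c in dataset.classifiers],
            "tree": [c.tree for c in dataset.classifiers],
            "leaf": [c.leaf for c in dataset.classifiers],
            "replica": [c.replica for c in dataset.classifiers],
        }
    )

    aligned = gpa(dataset, fit=config.fit)
    tangent = tangent_space_check(aligned)
    screen = outlier_screen(aligned, groups=cls_df["population"].to_numpy())
    pca = shape_pca(aligned)
    dist = np.sqrt(
        ((aligned.shapes[:, None, :] - aligned.shapes[None, :, :]) ** 2).sum(axis=2)
    )
    phenogram = upgma_phenogram(dist, labels=dataset.labels)

    anova_size = ProcrustesAnova(
        aligned.centroid_sizes, cls_df, response="size", df_convention=config.df_convention
    ).fit()
    anova_shape = ProcrustesAnova(
        aligned.shapes, cls_df, response="shape", df_convention=config.df_convention
    ).fit()

    ta = average_by_tree(aligned, cls_df)
    b = config.n_permutations
    seed = config.seed
    size_test = size_t_test(ta.sizes, ta.populations, n_perm=b, seed=seed)
    size_dummy = dummy_regression_test(ta.sizes, ta.populations, n_perm=b, seed=seed + 1)
    shape_tests = {
        "hotelling": hotelling_t2(ta.shapes, ta.populations),
        "mahalanobis": distance_permutation_test(
            ta.shapes, ta.populations, metric="mahalanobis", n_perm=b, seed=seed + 2
        ),
        "procrustes": distance_permutation_test(
            ta.shapes, ta.populations, metric="procrustes", n_perm=b, seed=seed + 3
        ),
        "shape_dummy": dummy_regression_test(ta.shapes, ta.populations, n_perm=b, seed=seed + 4),
    }
    discriminant = ShapeDiscriminant(ta.shapes, ta.populations).fit(cross_validate=True)

    allom = shape_size_regression(
        ta.shapes, ta.sizes, n_perm=b, use_log=config.use_log_size, seed=seed + 5
    )
    manc = mancova(ta.shapes, ta.sizes, ta.populations)
    slopes_p = float(manc.loc[manc["term"] == "slopes", "P"].iloc[0])
    corrected = size_correct(
        ta.shapes,
        ta.sizes,
        ta.populations,
        common_size=config.common_size,
        slopes_p=slopes_p,
        force=config.force_parallel,
    )
    corrected_tests = rerun_group_tests_on_corrected(corrected, n_perm=b, seed=seed + 6)

    # diagram geometry: consensus -> each population mean, magnified
    consensus = aligned.consensus_configuration()
    diagrams: dict[str, dict] = {}
    levels = np.unique(ta.populations)
    for g in levels:
        target = ta.shapes[ta.populations == g].mean(axis=0).reshape(-1, 2)
        entry = {}
        for kind in config.diagram_kinds:
            if kind == "grid":
                entry[kind] = make_grid(consensus, target, magnification=config.magnification)
            elif kind == "lollipop":
                entry[kind] = lollipops(consensus, target, magnification=config.magnification)
            elif kind == "wireframe" and dataset.wireframe:
                entry[kind] = warp_wireframe(
                    consensus, target, dataset.wireframe, magnification=config.magnification
                )
            elif kind == "outline" and dataset.outline is not None:
                entry[kind] = warp_outline(
                    consensus, target, dataset.outline, magnification=config.magnification
                )
        diagrams[str(g)] = entry

    bundle = ReportBundle(
        config=config,
        tangent_check=tangent,
        outlier_report=screen,
        pca=pca,
        phenogram=phenogram,
        anova_size=anova_size,
        anova_shape=anova_shape,
        tree_averaged=ta,
        size_test=size_test,
        size_dummy=size_dummy,
        shape_tests=shape_tests,
        discriminant=discriminant,
        allometry=allom,
        mancova_table=manc,
        size_corrected=corrected,
        corrected_tests=corrected_tests,
        diagrams=diagrams,
        metadata={
            "seed": seed,
            "version": _version,
            "df_convention": config.df_convention,
            "n_permutations": b,
            "fit": config.fit,
        },
    )
    _check_identities(bundle, aligned, cls_df)

    if config.output_dir:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dict(bundle.metadata)

    def frame(df: pd.DataFrame, name: str) -> None:
        df = df.copy()
        for key, val in meta.items():
            df.attrs[key] = val
        header = "# " + json.dumps(meta)
        with open(outdir / name, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, sep="\t", index=False)

    frame(bundle.anova_size.table, "anova_size.tsv")
    frame(bundle.anova_shape.table, "anova_shape.tsv")
    frame(bundle.mancova_table, "mancova.tsv")
    frame(bundle.discriminant.confusion_jackknife.reset_index(), "confusion_jackknife.tsv")
    frame(bundle.discriminant.confusion_resub.reset_index(), "confusion_resub.tsv")
    pd.DataFrame(
        {
            "eigenvalue": bundle.pca.eigenvalues,
            "pct_variance": bundle.pca.pct_variance,
        }
    ).to_csv(outdir / "pca_eigenvalues.tsv", sep="\t", index=False)
    (outdir / "phenogram.nwk").write_text(bundle.phenogram.to_newick() + "\n")
    summary = {
        "metadata": meta,
        "tangent_slope": bundle.tangent_check.slope,
        "tangent_correlation": bundle.tangent_check.correlation,
        "mean_distance_to_consensus": bundle.tangent_check.mean_distance,
        "max_distance_to_consensus": bundle.tangent_check.max_distance,
        "cophenetic_r": bundle.phenogram.cophenetic_r,
        "size_t": bundle.size_test.statistic,
        "size_t_p_perm": bundle.size_test.p_permutation,
        "hotelling_t2": bundle.shape_tests["hotelling"].statistic,
        "mahalanobis_d": bundle.shape_tests["hotelling"].mahalanobis_d,
        "procrustes_d": bundle.shape_tests["procrustes"].statistic,
        "jackknife_accuracy": bundle.discriminant.jackknife_accuracy,
        "allometry_pct_variance": bundle.allometry.pct_variance,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
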