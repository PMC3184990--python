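"""Synthetic leaf landmark data with the hierarchical variance
structure of the oak study design.

The generator emulates a balanced two-population sampling scheme — by
default 2 populations x 22 trees x 2 leaves x 2 replicas = 176
observations of an 11-landmark half-leaf — with additive tangent-space
shape effects at four nested levels (fixed population offsets, random
tree and leaf effects, digitizing noise), lognormal centroid sizes with
tree and leaf components, and a weak common allometric trend.  Labels
follow the ``Campo_T01_L1_R1`` filename convention, so they round-trip
through the classifier parser.

Effects are added in the tangent space at the template and mapped back,
which keeps the generating variance components directly comparable to
the ANOVA expectations; this small-perturbation construction is valid
only for small effect SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from leafgmm.io import LandmarkConfiguration, LandmarkDataset, parse_classifiers

#: character ranges matching the generated labels
LABEL_RANGES = {"population": (1, 5), "tree": (1, 9), "leaf": (1, 12), "replica": (15, 15)}


def template_leaf() -> np.ndarray:
    """A fixed 11-point half-leaf template (synthetic fixture).

    Eleven landmarks along the petiole, midrib and right margin of a
    stylized oak-like half leaf: petiole base and blade insertion, lobe
    tips and sinuses up the margin, and the apex.  Deterministic,
    centered on its centroid, scaled to unit centroid size, and
    non-collinear (TPS-fittable).
    """
    pts = np.array(
        [
            [0.00, 0.00],  # petiole base
            [0.00, 0.18],  # blade insertion
            [0.16, 0.24],  # first lobe tip
            [0.10, 0.38],  # first sinus
            [0.22, 0.48],  # second lobe tip
            [0.13, 0.60],  # second sinus
            [0.20, 0.72],  # third lobe tip
            [0.10, 0.82],  # third sinus
            [0.12, 0.90],  # fourth lobe tip
            [0.05, 0.96],  # subapical margin point
            [0.00, 1.02],  # apex
        ]
    )
    pts = pts - pts.mean(axis=0)
    pts /= np.sqrt((pts**2).sum())
    return pts


def _default_wireframe() -> list[tuple[int, int]]:
    return [(i, i + 1) for i in range(1, 11)] + [(2, 11)]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study design.

    Shape-effect SDs are per tangent-space coordinate (dimensionless
    Procrustes units); sizes are in mm.  The defaults are calibrated so
    the expected per-stratum sum-of-squares shares reproduce the study
    conditions: for shape roughly 3 % populations, 63 % trees, 34 %
    leaves and ~0.1 % digitizing error (mean specimen-to-consensus
    distance about 0.11 Procrustes units); for size roughly 6 % / 55 %
    / 39 % / <0.1 % around a 70 mm mean; plus a weak allometric trend
    shared by the two populations (a few percent of tree-level shape
    variance).  See :func:`expected_stratum_shares` for the closed-form
    expectations these defaults imply.
    """

    template: np.ndarray = field(default_factory=template_leaf)
    population_names: tuple[str, ...] = ("Campo", "Busso")
    trees_per_population: int = 22
    leaves_per_tree: int = 2
    replicas_per_leaf: int = 2
    sigma_tree: float = 0.0154
    sigma_leaf: float = 0.0225
    sigma_error: float = 0.0012
    population_offset_scale: float = 0.0132  # each population at +/- this along a fixed direction
    size_mean_per_population: tuple[float, ...] = (70.5, 69.5)  # mm
    sigma_size_tree: float = 0.0137  # lognormal SD of the tree size factor
    sigma_size_leaf: float = 0.0286  # lognormal SD of the leaf size factor
    sigma_size_error: float = 0.0005  # replica (digitizing) size noise factor
    allometry_scale: float = 0.0144  # shape change per mm of centroid size
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sigma_tree",
            "sigma_leaf",
            "sigma_error",
            "sigma_size_tree",
            "sigma_size_leaf",
            "sigma_size_error",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.size_mean_per_population) != len(self.population_names):
            raise ValueError("one mean size per population required")
        if any(m <= 0 for m in self.size_mean_per_population):
            raise ValueError("population mean sizes must be positive")

    @property
    def n_populations(self) -> int:
        return len(self.population_names)

    @property
    def n_observations(self) -> int:
        return (
            self.n_populations
            * self.trees_per_population
            * self.leaves_per_tree
            * self.replicas_per_leaf
        )


def _tangent_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the (2k - 4)-dim tangent space at the
    template, so isotropic tangent noise has exactly the nominal
    per-dimension SD."""
    k = template.shape[0]
    c = template.ravel()
    rot = np.empty_like(c)
    rot[0::2] = -template[:, 1]
    rot[1::2] = template[:, 0]
    tx = np.zeros(2 * k)
    tx[0::2] = 1.0
    ty = np.zeros(2 * k)
    ty[1::2] = 1.0
    sim = np.column_stack([tx, ty, c, rot])
    q, _ = np.linalg.qr(sim)
    proj = np.eye(2 * k) - q @ q.T
    vals, vecs = np.linalg.eigh(proj)
    return vecs[:, vals > 0.5]  # (2k, 2k-4)


def generate_dataset(spec: SyntheticSpec | None = None, seed: int | None = None) -> LandmarkDataset:
    """Generate a balanced hierarchical landmark dataset.

    Per observation the shape is

        template (+ population offset + tree effect + leaf effect
                 + replica digitizing noise + allometric term)

    with all effects drawn in the tangent space at the template, and the
    configuration in mm is the shape scaled by the specimen's centroid
    size.  Replicas of a leaf share its shape and size exactly except
    for the digitizing noise.  Identical spec and seed give bit-identical
    output.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    basis = _tangent_basis(spec.template)
    dim = basis.shape[1]
    grand_mean_size = float(np.mean(spec.size_mean_per_population))

    # fixed, reproducible directions for population offsets and allometry
    dir_rng = np.random.default_rng(12345)
    pop_dirs = []
    base_dir = dir_rng.standard_normal(dim)
    base_dir /= np.linalg.norm(base_dir)
    for i in range(spec.n_populations):
        sign = 1.0 if i % 2 == 0 else -1.0
        pop_dirs.append(sign * spec.population_offset_scale * (basis @ base_dir))
    allo_dir = dir_rng.standard_normal(dim)
    allo_dir /= np.linalg.norm(allo_dir)
    allometry_vector = spec.allometry_scale * (basis @ allo_dir)

    configs: list[LandmarkConfiguration] = []
    for i_pop, pop in enumerate(spec.population_names):
        mean_size = spec.size_mean_per_population[i_pop]
        for i_tree in range(1, spec.trees_per_population + 1):
            tree_shape = basis @ (spec.sigma_tree * rng.standard_normal(dim))
            tree_size_factor = np.exp(spec.sigma_size_tree * rng.standard_normal())
            for i_leaf in range(1, spec.leaves_per_tree + 1):
                leaf_shape = basis @ (spec.sigma_leaf * rng.standard_normal(dim))
                leaf_size = mean_size * tree_size_factor * np.exp(
                    spec.sigma_size_leaf * rng.standard_normal()
                )
                for i_rep in range(1, spec.replicas_per_leaf + 1):
                    noise = basis @ (spec.sigma_error * rng.standard_normal(dim))
                    size = leaf_size * np.exp(spec.sigma_size_error * rng.standard_normal())
                    tangent = (
                        pop_dirs[i_pop]
                        + tree_shape
                        + leaf_shape
                        + noise
                        + allometry_vector * (size - grand_mean_size)
                    )
                    shape = spec.template + tangent.reshape(-1, 2)
                    label = f"{pop}_T{i_tree:02d}_L{i_leaf}_R{i_rep}"
                    configs.append(
                        LandmarkConfiguration(label=label, coords=shape * size)
                    )
    classifiers = parse_classifiers([c.label for c in configs], LABEL_RANGES)
    return LandmarkDataset(
        configurations=configs, classifiers=classifiers, wireframe=_default_wireframe()
    )


def null_dataset(
    spec: SyntheticSpec | None = None, null: str = "no_group_difference", seed: int | None = None
) -> LandmarkDataset:
    """The same generator with one named effect forced to zero.

    ``no_group_difference``: no population shape offset and equal mean
    sizes; ``no_allometry``: zero allometric vector; ``equal_slopes``:
    identical (the default already shares one allometric vector, so this
    null keeps it and removes nothing else) — useful for slope-term
    type-I calibration.
    """
    spec = spec or SyntheticSpec()
    if null == "no_group_difference":
        mean = float(np.mean(spec.size_mean_per_population))
        spec = replace(
            spec,
            population_offset_scale=0.0,
            size_mean_per_population=tuple(mean for _ in spec.population_names),
        )
    elif null == "no_allometry":
        spec = replace(spec, allometry_scale=0.0)
    elif null == "equal_slopes":
        pass  # the generator's single shared allometric vector is the null
    else:
        raise ValueError(f"unknown null scenario {null!r}")
    return generate_dataset(spec, seed=seed)


def expected_stratum_shares(spec: SyntheticSpec | None = None, response: str = "shape") -> dict[str, float]:
    """Expected percent of total SS per ANOVA stratum under the
    generating model.

    Closed-form expectations of the sequential (hierarchical) sums of
    squares for the balanced design, expressed as shares summing to
    100.  For each stratum the group means absorb a ``1/m`` fraction of
    the variance of every level nested below it, which is why a tree
    stratum can dominate even when the per-coordinate leaf SD exceeds
    the tree SD — the same accumulation that operates in the real
    ANOVA.  Used by the parameter-recovery tests to compare the
    recovered pct-SS ordering against the generator's own.
    """
    spec = spec or SyntheticSpec()
    if response not in ("shape", "size"):
        raise ValueError("response must be 'shape' or 'size'")
    d = 2 * spec.template.shape[0] - 4
    P = spec.n_populations
    T = spec.trees_per_population
    L = spec.leaves_per_tree
    R = spec.replicas_per_leaf

    mean_size = float(np.mean(spec.size_mean_per_population))
    # per-observation size variances by level (lognormal factors, small-sigma)
    vs_tree = (mean_size * spec.sigma_size_tree) ** 2
    vs_leaf = (mean_size * spec.sigma_size_leaf) ** 2
    vs_err = (mean_size * spec.sigma_size_error) ** 2
    sizes = np.asarray(spec.size_mean_per_population, float)
    vs_pop = float(((sizes - sizes.mean()) ** 2).mean())

    if response == "size":
        v_pop, v_tree, v_leaf, v_err = vs_pop, vs_tree, vs_leaf, vs_err
    else:
        a2 = spec.allometry_scale**2
        v_tree = d * spec.sigma_tree**2 + a2 * vs_tree
        v_leaf = d * spec.sigma_leaf**2 + a2 * vs_leaf
        v_err = d * spec.sigma_error**2 + a2 * vs_err
        v_pop = spec.population_offset_scale**2 + a2 * vs_pop

    # expected sequential SS per observation
    e_err = (1 - 1 / R) * v_err
    e_leaf = (1 - 1 / L) * (v_leaf + v_err / R)
    e_tree = (1 - 1 / T) * (v_tree + v_leaf / L + v_err / (L * R))
    e_pop = v_pop + (1 - 1 / P) * (v_tree / T + v_leaf / (T * L) + v_err / (T * L * R))
    total = e_pop + e_tree + e_leaf + e_err
    return {
        "populations": 100 * e_pop / total,
        "trees": 100 * e_tree / total,
        "leaves": 100 * e_leaf / total,
        "error": 100 * e_err / total,
    }
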