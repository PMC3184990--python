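"""Procrustes superimposition of 2D landmark configurations.

Implements centroid size, generalized Procrustes analysis (GPA) with
orthogonal projection into the tangent space at the consensus, tangent
approximation diagnostics, and the two-point (Bookstein baseline)
registration used to demonstrate superimposition (in)dependence.

Conventions
-----------
* Shape vectors are landmark-major interleaved: ``(x1, y1, x2, y2, ...)``.
* The fit is a *partial* Procrustes fit: every configuration keeps unit
  centroid size; no cosine rescaling is applied.  A full fit (rescaling
  each specimen by the cosine of its Procrustes distance to the
  consensus) is available via ``fit="full"``.
* Rotations are proper 2D rotations; reflections are never allowed.
* After convergence the consensus is rotated onto its principal axes,
  with the 180-degree ambiguity resolved by making its first nonzero
  coordinate positive, so results are reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from leafgmm.io import LandmarkConfiguration, LandmarkDataset

_CONVERGENCE_TOL = 1e-10
_MAX_ITERATIONS = 100


def as_coords_array(data) -> np.ndarray:
    """Coerce a dataset / configuration list / array to (n, k, 2)."""
    if isinstance(data, LandmarkDataset):
        return data.coords_array()
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], LandmarkConfiguration):
        return np.stack([c.coords for c in data])
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:  # single configuration
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError(f"expected (n, k, 2) landmark array, got shape {arr.shape}")
    return arr


def centroid_size(config) -> float:
    """Centroid size: square root of the summed squared distances of the
    landmarks from their centroid.

    Invariant under rotation and translation and homogeneous of degree 1
    under uniform scaling.  Raises for a degenerate (all points
    coincident) configuration.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"expected a (k, 2) configuration, got {coords.shape}")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide (centroid size 0)")
    return cs


@dataclass
class AlignedShapes:
    """Tangent-space Procrustes coordinates produced by :func:`gpa`.

    Attributes
    ----------
    shapes : (n, 2k) array
        Tangent-space shape coordinates (consensus at the point of
        tangency).
    mean_shape : (2k,) array
        The unit-size consensus configuration (flattened).
    centroid_sizes : (n,) array
        Centroid sizes of the raw configurations, in mm.
    preshapes : (n, 2k) array
        Aligned unit-size pre-projection coordinates; kept so Riemannian
        distances (arc lengths) can be computed exactly.
    """

    shapes: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    n_iterations: int
    converged: bool
    preshapes: np.ndarray

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1] // 2

    def configurations(self) -> np.ndarray:
        """Tangent coordinates reshaped to (n, k, 2)."""
        return self.shapes.reshape(self.n, self.k, 2)

    def consensus_configuration(self) -> np.ndarray:
        return self.mean_shape.reshape(self.k, 2)


def _optimal_rotation_angles(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares proper-rotation angle of each (k,2) shape onto target."""
    zc = target[:, 0] + 1j * target[:, 1]
    zs = shapes[..., 0] + 1j * shapes[..., 1]
    return np.angle((np.conj(zs) * zc).sum(axis=-1))


def _rotate(shapes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    zs = shapes[..., 0] + 1j * shapes[..., 1]
    zr = zs * np.exp(1j * angles)[..., None]
    return np.stack([zr.real, zr.imag], axis=-1)


def gpa(data, fit: str = "partial") -> AlignedShapes:
    """Generalized Procrustes analysis with tangent-space projection.

    Each configuration is centered, scaled to unit centroid size, and
    iteratively rotated to the running consensus by least squares until
    the consensus stabilizes; the shapes are then orthogonally projected
    onto the Euclidean space tangent to the shape space at the consensus.

    Parameters
    ----------
    data : LandmarkDataset, list of LandmarkConfiguration, or (n, k, 2) array
    fit : {"partial", "full"}
        ``partial`` (default) keeps every specimen at unit centroid
        size; ``full`` additionally rescales each specimen by
        ``cos(rho)``, its full-fit optimal scale.
    """
    coords = as_coords_array(data)
    n, k, _ = coords.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if fit not in ("partial", "full"):
        raise ValueError(f"fit must be 'partial' or 'full', got {fit!r}")

    centered = coords - coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    if np.any(sizes == 0):
        bad = int(np.argmin(sizes))
        raise ValueError(f"degenerate configuration at index {bad} (centroid size 0)")
    pre = centered / sizes[:, None, None]

    consensus = pre[0].copy()
    consensus /= np.sqrt((consensus**2).sum())
    n_iter = 0
    converged = False
    for n_iter in range(1, _MAX_ITERATIONS + 1):
        pre = _rotate(pre, _optimal_rotation_angles(pre, consensus))
        new_consensus = pre.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        change = ((new_consensus - consensus) ** 2).sum()
        consensus = new_consensus
        if change < _CONVERGENCE_TOL:
            converged = True
            break

    # principal-axis alignment of the consensus, applied to all shapes
    cov = consensus.T @ consensus
    theta = 0.5 * np.arctan2(2 * cov[0, 1], cov[0, 0] - cov[1, 1])
    rot = -theta
    candidate = _rotate(consensus[None], np.array([rot]))[0]
    flat = candidate.ravel()
    first_nonzero = flat[np.nonzero(np.abs(flat) > 1e-12)[0][0]]
    if first_nonzero < 0:
        rot += np.pi  # 180-degree rotation, not a reflection
    consensus = _rotate(consensus[None], np.array([rot]))[0]
    pre = _rotate(pre, np.full(n, rot))
    # final re-rotation of every specimen onto the fixed consensus
    pre = _rotate(pre, _optimal_rotation_angles(pre, consensus))

    c = consensus.ravel()
    x = pre.reshape(n, -1)
    if fit == "full":
        x = x * (x @ c)[:, None]
    # orthogonal projection onto the tangent plane at c
    tangent = x - np.outer(x @ c - 1.0, c)

    return AlignedShapes(
        shapes=tangent,
        mean_shape=c,
        centroid_sizes=sizes,
        n_iterations=n_iter,
        converged=converged,
        preshapes=x,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the difference of two tangent-space shape
    vectors from a common alignment."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"shape vector length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


@dataclass
class TangentCheck:
    """Diagnostics of the tangent-space approximation.

    ``slope`` and ``correlation`` come from a no-intercept regression of
    tangent Euclidean distances on Riemannian Procrustes distances to the
    consensus; both near 1 means the linearization is excellent.
    """

    slope: float
    correlation: float
    procrustes_distances: np.ndarray
    tangent_distances: np.ndarray

    @property
    def mean_distance(self) -> float:
        return float(self.procrustes_distances.mean())

    @property
    def max_distance(self) -> float:
        return float(self.procrustes_distances.max())


def tangent_space_check(data) -> TangentCheck:
    """Regress tangent-space Euclidean distances (through the origin)
    onto Riemannian Procrustes distances to the consensus.

    The Riemannian distance of each specimen is ``rho = arccos`` of the
    inner product of its aligned unit-size pre-shape with the unit
    consensus; the Euclidean distance is measured after orthogonal
    projection, hence equals ``sin(rho)`` and the slope can never exceed
    1.
    """
    aligned = data if isinstance(data, AlignedShapes) else gpa(data)
    if aligned.n < 3:
        raise ValueError("tangent check needs at least 3 specimens")
    c = aligned.mean_shape
    cosr = np.clip(aligned.preshapes @ c, -1.0, 1.0)
    rho = np.arccos(cosr)
    d_tan = np.linalg.norm(aligned.shapes - c, axis=1)
    ss_rho = float((rho**2).sum())
    # arccos has a ~1e-8 noise floor near 1; below that there is no real variation
    if float(rho.mean()) < 1e-7:
        raise ValueError("no shape variation: all specimens identical to the consensus")
    slope = float((d_tan * rho).sum() / ss_rho)
    corr = float((d_tan * rho).sum() / np.sqrt(ss_rho * (d_tan**2).sum()))
    return TangentCheck(
        slope=slope, correlation=corr, procrustes_distances=rho, tangent_distances=d_tan
    )


def baseline_superimpose(data, baseline: tuple[int, int]) -> np.ndarray:
    """Bookstein two-point registration.

    Translates, rotates and rescales every configuration so that the
    first baseline landmark lands exactly on (0, 0) and the second on
    (1, 0).  ``baseline`` uses 1-based landmark indices.
    """
    coords = as_coords_array(data)
    n, k, _ = coords.shape
    i, j = baseline
    if i == j:
        raise ValueError("baseline landmarks must be distinct")
    if not (1 <= i <= k and 1 <= j <= k):
        raise ValueError(f"baseline indices ({i}, {j}) outside 1..{k}")
    z = coords[..., 0] + 1j * coords[..., 1]
    denom = z[:, j - 1] - z[:, i - 1]
    bad = np.nonzero(np.abs(denom) == 0)[0]
    if bad.size:
        raise ValueError(f"coincident baseline points in specimen index {int(bad[0])}")
    w = (z - z[:, i - 1][:, None]) / denom[:, None]
    return np.stack([w.real, w.imag], axis=-1)
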