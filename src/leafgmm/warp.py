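"""Thin-plate-spline warps and visualization geometry.

The TPS is the interpolating map of the plane that takes the reference
landmarks exactly onto the target landmarks while minimizing an
idealized bending energy.  The kernel convention here is
``U(r) = r^2 log r^2`` with ``U(0) = 0`` (both ``r^2 log r`` and
``r^2 log r^2`` appear in the literature; they differ by a factor of 2
absorbed into the weights).

This module produces geometry only — deformation-grid polylines, warped
outlines/wireframes, displacement (lollipop) segments, Jacobian
expansion factors, partial-warp and uniform-component scores — ready
for any plotting backend; no rendering happens here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from leafgmm.superimpose import AlignedShapes


def _kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2, with U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


@dataclass
class TpsCoefficients:
    """A fitted thin-plate spline from ``reference`` to a target.

    ``affine`` is 3 x 2 (constant, x and y terms per output coordinate);
    ``weights`` is k x 2 and satisfies the side conditions (weights sum
    to zero and are orthogonal to the reference coordinates), which make
    the warp behave affinely at infinity.  ``bending_energy`` is
    ``trace(W^T K W)``; it is zero iff the map is affine.
    """

    reference: np.ndarray  # (k, 2)
    weights: np.ndarray  # (k, 2)
    affine: np.ndarray  # (3, 2)
    bending_energy: float


def tps_fit(reference: np.ndarray, target: np.ndarray) -> TpsCoefficients:
    """Fit the TPS mapping ``reference`` landmarks onto ``target``.

    Solves the standard L-matrix system; raises for a collinear (or
    otherwise singular) reference.  Needs k >= 3; with exactly 3
    landmarks the map degenerates to the affine map.
    """
    ref = np.asarray(reference, float)
    tgt = np.asarray(target, float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("reference and target must both be (k, 2)")
    k = ref.shape[0]
    if k < 3:
        raise ValueError("TPS needs at least 3 landmarks")
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    K = _kernel(d2)
    P = np.column_stack([np.ones(k), ref])
    if np.linalg.matrix_rank(P, tol=1e-10 * max(np.abs(ref).max(), 1.0)) < 3:
        raise ValueError("singular TPS system: reference landmarks are collinear")
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError:
        raise ValueError("singular TPS system: reference landmarks are collinear or duplicated")
    if not np.all(np.isfinite(sol)):
        raise ValueError("singular TPS system: reference landmarks are collinear or duplicated")
    w = sol[:k]
    a = sol[k:]
    be = float(np.einsum("id,ij,jd->", w, K, w))
    return TpsCoefficients(reference=ref, weights=w, affine=a, bending_energy=max(be, 0.0))


def tps_warp_points(coeffs: TpsCoefficients, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted warp at arbitrary points:
    ``f(p) = A [1, x, y] + sum_i w_i U(|p - ref_i|)``."""
    pts = np.atleast_2d(np.asarray(points, float))
    d2 = ((pts[:, None, :] - coeffs.reference[None, :, :]) ** 2).sum(axis=2)
    u = _kernel(d2)
    P = np.column_stack([np.ones(pts.shape[0]), pts])
    return P @ coeffs.affine + u @ coeffs.weights


def jacobian_expansion(coeffs: TpsCoefficients, points: np.ndarray) -> np.ndarray:
    """Determinant of the analytic Jacobian of the warp at each point.

    Values > 1 mark local area expansion, values in (0, 1) contraction.
    Negative determinants (grid fold-over, possible at large
    magnifications) are returned as-is with a warning.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    diff = pts[:, None, :] - coeffs.reference[None, :, :]  # (m, k, 2)
    r2 = (diff**2).sum(axis=2)
    # dU/dx = 2 (x - xi) (log r^2 + 1); zero at r = 0
    factor = np.zeros_like(r2)
    nz = r2 > 0
    factor[nz] = 2.0 * (np.log(r2[nz]) + 1.0)
    du = factor[:, :, None] * diff  # (m, k, 2) gradient of U_i at each point
    # J[m] = affine linear part + sum_i outer(w_i, grad U_i)
    jac = np.empty((pts.shape[0], 2, 2))
    jac[:] = coeffs.affine[1:].T  # rows: output coord; cols: input coord
    jac += np.einsum("id,mic->mdc", coeffs.weights, du)
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    if np.any(det <= 0):
        warnings.warn(
            "non-positive Jacobian determinant: the warp folds over itself "
            "(beware of over-magnified differences)",
            stacklevel=2,
        )
    return det


@dataclass
class ShapeDiagram:
    """Plot-ready geometry for one visualization.

    ``kind`` is one of grid / outline / wireframe / lollipop;
    ``polylines`` are lists of (m, 2) vertex arrays for the reference
    and for the (possibly magnified) target frame.  For grids,
    ``grid_nodes`` and ``jacobian`` carry the node positions and the
    local expansion factor at each node.
    """

    kind: str
    reference_polylines: list[np.ndarray]
    target_polylines: list[np.ndarray]
    magnification: float = 1.0
    grid_nodes: np.ndarray | None = None
    jacobian: np.ndarray | None = None


def magnify(reference: np.ndarray, target: np.ndarray, m: float) -> np.ndarray:
    """Scalar magnification of shape differences:
    ``reference + m (target - reference)``.  ``m = 1`` is the target
    itself, ``m = 0`` the reference."""
    reference = np.asarray(reference, float)
    target = np.asarray(target, float)
    if reference.shape != target.shape:
        raise ValueError("reference and target must have the same shape")
    if m <= 0 and m != 0.0:
        raise ValueError("magnification must be non-negative")
    return reference + m * (target - reference)


def make_grid(
    reference: np.ndarray,
    target: np.ndarray,
    n_cells: int = 20,
    margin: float = 0.1,
    magnification: float = 1.0,
    points_per_edge: int = 10,
) -> ShapeDiagram:
    """Deformation grid: a square grid over the reference bounding box
    (expanded by ``margin``) and its image under the TPS to the
    (magnified) target, with Jacobian expansion factors at the nodes."""
    ref = np.asarray(reference, float)
    tgt = magnify(ref, np.asarray(target, float), magnification)
    coeffs = tps_fit(ref, tgt)
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    span = hi - lo
    lo = lo - margin * span
    hi = hi + margin * span
    xs = np.linspace(lo[0], hi[0], n_cells + 1)
    ys = np.linspace(lo[1], hi[1], n_cells + 1)
    dense_x = np.linspace(lo[0], hi[0], n_cells * points_per_edge + 1)
    dense_y = np.linspace(lo[1], hi[1], n_cells * points_per_edge + 1)

    ref_lines: list[np.ndarray] = []
    for x in xs:
        ref_lines.append(np.column_stack([np.full_like(dense_y, x), dense_y]))
    for y in ys:
        ref_lines.append(np.column_stack([dense_x, np.full_like(dense_x, y)]))
    tgt_lines = [tps_warp_points(coeffs, line) for line in ref_lines]

    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    jac = jacobian_expansion(coeffs, nodes)
    return ShapeDiagram(
        kind="grid",
        reference_polylines=ref_lines,
        target_polylines=tgt_lines,
        magnification=magnification,
        grid_nodes=nodes,
        jacobian=jac,
    )


def warp_outline(
    reference: np.ndarray, target: np.ndarray, outline: np.ndarray, magnification: float = 1.0
) -> ShapeDiagram:
    """Warp an outline polyline drawn in the reference frame onto the
    (magnified) target configuration."""
    ref = np.asarray(reference, float)
    tgt = magnify(ref, np.asarray(target, float), magnification)
    outline = np.asarray(outline, float)
    coeffs = tps_fit(ref, tgt)
    return ShapeDiagram(
        kind="outline",
        reference_polylines=[outline],
        target_polylines=[tps_warp_points(coeffs, outline)],
        magnification=magnification,
    )


def warp_wireframe(
    reference: np.ndarray,
    target: np.ndarray,
    links: list[tuple[int, int]],
    magnification: float = 1.0,
) -> ShapeDiagram:
    """Straight-segment wireframe (1-based landmark index pairs) drawn
    on the reference and on the magnified target."""
    ref = np.asarray(reference, float)
    tgt = magnify(ref, np.asarray(target, float), magnification)
    k = ref.shape[0]
    ref_segs, tgt_segs = [], []
    for a, b in links:
        if not (1 <= a <= k and 1 <= b <= k):
            raise ValueError(f"wireframe link ({a}, {b}) outside 1..{k}")
        ref_segs.append(ref[[a - 1, b - 1]])
        tgt_segs.append(tgt[[a - 1, b - 1]])
    return ShapeDiagram(
        kind="wireframe",
        reference_polylines=ref_segs,
        target_polylines=tgt_segs,
        magnification=magnification,
    )


def lollipops(reference: np.ndarray, target: np.ndarray, magnification: float = 1.0) -> ShapeDiagram:
    """Displacement vectors: one segment from each reference landmark to
    the same landmark in the (magnified) target."""
    ref = np.asarray(reference, float)
    tgt = magnify(ref, np.asarray(target, float), magnification)
    segs = [np.vstack([ref[i], tgt[i]]) for i in range(ref.shape[0])]
    return ShapeDiagram(
        kind="lollipop",
        reference_polylines=[ref],
        target_polylines=segs,
        magnification=magnification,
    )


@dataclass
class PartialWarpScores:
    """Projections of shape deviations onto the principal-warp and
    uniform bases.

    ``partial_warp_scores`` is (n, 2(k-3)); ``uniform_scores`` is
    (n, 2).  Together the bases span the 2k - 4 dimensional tangent
    space, so pairwise distances computed from all scores equal the
    tangent-space Procrustes distances.
    """

    partial_warp_scores: np.ndarray
    uniform_scores: np.ndarray
    principal_warps: np.ndarray  # (k, k-3) eigenvectors of the bending-energy matrix
    bending_eigenvalues: np.ndarray  # (k-3,) nonzero eigenvalues
    uniform_basis: np.ndarray  # (2k, 2)


def partial_warps(reference: np.ndarray, aligned: AlignedShapes | np.ndarray) -> PartialWarpScores:
    """Principal warps of the reference, partial-warp scores of the
    aligned shapes, and the uniform (affine) component scores.

    The bending-energy matrix is the upper-left k x k block of the
    inverse of the TPS L-matrix built on the reference (normally the
    consensus).  Its k - 3 nonzero-eigenvalue eigenvectors are the
    principal warps; projecting each specimen's deviation from the
    reference onto them (x and y separately) gives the partial-warp
    scores.  The uniform components are an orthonormal basis of the
    2-dimensional complement of the partial-warp subspace within the
    tangent space, computed numerically.
    """
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    if k < 4:
        raise ValueError("partial warps need at least 4 landmarks")
    shapes = aligned.shapes if isinstance(aligned, AlignedShapes) else np.asarray(aligned, float)
    if shapes.ndim != 2 or shapes.shape[1] != 2 * k:
        raise ValueError(f"shapes must be (n, {2 * k})")

    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    K = _kernel(d2)
    P = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    try:
        L_inv = np.linalg.inv(L)
    except np.linalg.LinAlgError:
        raise ValueError("collinear reference: bending-energy matrix undefined")
    be = L_inv[:k, :k]
    be = (be + be.T) / 2.0
    evals, evecs = np.linalg.eigh(be)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    nonzero = evals > 1e-10 * max(abs(evals[0]), 1e-300)
    n_pw = int(nonzero.sum())
    if n_pw != k - 3:
        # fall back to the theoretical count: the 3 affine directions are null
        n_pw = k - 3
    pw = evecs[:, :n_pw]  # (k, k-3)

    # basis vectors in R^{2k}: each principal warp applied to x and to y
    basis_pw = np.zeros((2 * k, 2 * n_pw))
    basis_pw[0::2, 0::2] = pw  # x components
    basis_pw[1::2, 1::2] = pw  # y components

    # similarity directions at the reference (translation x/y, scale, rotation)
    c = ref.ravel()
    rot = np.empty_like(c)
    rot[0::2] = -ref[:, 1]
    rot[1::2] = ref[:, 0]
    tx = np.zeros(2 * k)
    tx[0::2] = 1.0
    ty = np.zeros(2 * k)
    ty[1::2] = 1.0
    known = np.column_stack([basis_pw, tx, ty, c, rot])
    # uniform basis: orthonormal complement of `known` in R^{2k}
    q, _ = np.linalg.qr(known)
    proj = np.eye(2 * k) - q @ q.T
    u_vals, u_vecs = np.linalg.eigh(proj)
    uniform = u_vecs[:, u_vals > 0.5]
    if uniform.shape[1] != 2:
        raise ValueError(
            f"expected a 2-dimensional uniform subspace, found {uniform.shape[1]}"
        )

    dev = shapes - c
    return PartialWarpScores(
        partial_warp_scores=dev @ basis_pw,
        uniform_scores=dev @ uniform,
        principal_warps=pw,
        bending_eigenvalues=evals[:n_pw],
        uniform_basis=uniform,
    )
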