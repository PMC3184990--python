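"""Thin-plate splines, diagram geometry, partial warps."""

import numpy as np
import pytest

from leafgmm.superimpose import baseline_superimpose, gpa
from leafgmm.synthetic import template_leaf
from leafgmm.warp import (
    jacobian_expansion,
    lollipops,
    magnify,
    make_grid,
    partial_warps,
    tps_fit,
    tps_warp_points,
    warp_outline,
    warp_wireframe,
)

REF = template_leaf() * 10.0


def tps_eval_oracle(ref, weights, affine, points):
    """Direct per-point evaluation of the TPS formula, independent of
    the vectorized implementation."""
    out = np.zeros((len(points), 2))
    for m, (x, y) in enumerate(points):
        for d in range(2):
            val = affine[0, d] + affine[1, d] * x + affine[2, d] * y
            for i, (rx, ry) in enumerate(ref):
                r2 = (x - rx) ** 2 + (y - ry) ** 2
                if r2 > 0:
                    val += weights[i, d] * r2 * np.log(r2)
            out[m, d] = val
    return out


class TestTpsFit:
    def test_identity_warp(self):
        c = tps_fit(REF, REF)
        np.testing.assert_allclose(c.weights, 0.0, atol=1e-9)
        np.testing.assert_allclose(c.affine, [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]], atol=1e-9)
        assert c.bending_energy == pytest.approx(0.0, abs=1e-12)

    def test_pure_shear_has_zero_bending(self):
        shear = REF @ np.array([[1.0, 0.3], [0.0, 1.0]])
        c = tps_fit(REF, shear)
        np.testing.assert_allclose(c.weights, 0.0, atol=1e-8)
        assert c.bending_energy == pytest.approx(0.0, abs=1e-10)

    def test_interpolation_exact_at_landmarks(self, rng):
        for _ in range(5):
            target = REF + rng.normal(0, 0.5, size=REF.shape)
            c = tps_fit(REF, target)
            np.testing.assert_allclose(tps_warp_points(c, REF), target, atol=1e-9)

    def test_nonaffine_target_has_positive_bending(self, rng):
        target = REF + rng.normal(0, 0.5, size=REF.shape)
        assert tps_fit(REF, target).bending_energy > 1e-6

    def test_collinear_reference_raises(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="collinear"):
            tps_fit(line, line + 1.0)


class TestWarpPoints:
    def test_matches_direct_formula_oracle(self, rng):
        target = REF + rng.normal(0, 0.4, size=REF.shape)
        c = tps_fit(REF, target)
        probes = rng.uniform(-3, 3, size=(25, 2))
        np.testing.assert_allclose(
            tps_warp_points(c, probes),
            tps_eval_oracle(REF, c.weights, c.affine, probes),
            atol=1e-9,
        )

    def test_smooth_by_finite_differences(self, rng):
        """The warp has continuous first derivatives: central-difference
        gradients converge."""
        target = REF + rng.normal(0, 0.3, size=REF.shape)
        c = tps_fit(REF, target)
        p = np.array([[1.3, -0.7]])
        for h in (1e-4, 1e-5):
            gx = (tps_warp_points(c, p + [h, 0]) - tps_warp_points(c, p - [h, 0])) / (2 * h)
            assert np.all(np.isfinite(gx))


class TestJacobian:
    def test_identity_is_one_everywhere(self, rng):
        c = tps_fit(REF, REF)
        probes = rng.uniform(-2, 2, size=(30, 2))
        np.testing.assert_allclose(jacobian_expansion(c, probes), 1.0, atol=1e-9)

    def test_uniform_scaling_gives_c_squared(self, rng):
        c = tps_fit(REF, REF * 1.7)
        probes = rng.uniform(-2, 2, size=(10, 2))
        np.testing.assert_allclose(jacobian_expansion(c, probes), 1.7**2, atol=1e-8)

    def test_matches_central_differences(self, rng):
        target = REF + rng.normal(0, 0.4, size=REF.shape)
        c = tps_fit(REF, target)
        probes = rng.uniform(-2, 2, size=(12, 2))
        det_analytic = jacobian_expansion(c, probes)
        h = 1e-6
        for m, p in enumerate(probes):
            fx = (tps_warp_points(c, [p + [h, 0]]) - tps_warp_points(c, [p - [h, 0]])) / (2 * h)
            fy = (tps_warp_points(c, [p + [0, h]]) - tps_warp_points(c, [p - [0, h]])) / (2 * h)
            det_fd = fx[0, 0] * fy[0, 1] - fx[0, 1] * fy[0, 0]
            assert det_analytic[m] == pytest.approx(det_fd, abs=1e-6)

    def test_fold_over_warns(self, rng):
        target = REF.copy()
        target[4] = REF[5] + (REF[5] - REF[4]) * 3  # violent local inversion
        c = tps_fit(REF, target)
        probes = np.linspace(REF.min(axis=0), REF.max(axis=0), 50)
        with pytest.warns(UserWarning, match="folds over"):
            det = jacobian_expansion(c, probes)
        assert np.any(det <= 0)


class TestDiagrams:
    def test_lollipop_lengths_are_landmark_displacements(self, rng):
        target = REF + rng.normal(0, 0.3, size=REF.shape)
        dia = lollipops(REF, target)
        lengths = [np.linalg.norm(seg[1] - seg[0]) for seg in dia.target_polylines]
        np.testing.assert_allclose(lengths, np.linalg.norm(target - REF, axis=1), atol=1e-12)

    def test_identity_grid_is_straight(self):
        dia = make_grid(REF, REF, n_cells=5)
        for before, after in zip(dia.reference_polylines, dia.target_polylines):
            np.testing.assert_allclose(after, before, atol=1e-8)
        np.testing.assert_allclose(dia.jacobian, 1.0, atol=1e-8)

    def test_translated_outline_is_translated(self):
        outline = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        dia = warp_outline(REF, REF + [2.0, -1.0], outline)
        np.testing.assert_allclose(dia.target_polylines[0], outline + [2.0, -1.0], atol=1e-8)

    def test_wireframe_validates_indices(self):
        with pytest.raises(ValueError, match="wireframe"):
            warp_wireframe(REF, REF, [(1, 99)])

    def test_magnify_endpoints(self, rng):
        target = REF + rng.normal(0, 0.2, size=REF.shape)
        np.testing.assert_array_equal(magnify(REF, target, 1.0), target)
        np.testing.assert_array_equal(magnify(REF, target, 0.0), REF)

    def test_magnify_matches_pc_score_doubling(self, aligned):
        """Doubling the magnification of a shape at PC1 score s equals
        the shape at PC1 score 2s."""
        from leafgmm.ordination import shape_pca

        pca = shape_pca(aligned)
        mean = aligned.shapes.mean(axis=0)
        at = lambda s: (mean + s * pca.eigenvectors[:, 0]).reshape(-1, 2)
        doubled = magnify(mean.reshape(-1, 2), at(0.05), 2.0)
        np.testing.assert_allclose(doubled, at(0.10), atol=1e-12)

    def test_magnify_invertible(self, rng):
        target = REF + rng.normal(0, 0.2, size=REF.shape)
        m = 3.0
        mag = magnify(REF, target, m)
        np.testing.assert_allclose(magnify(REF, mag, 1 / m), target, atol=1e-12)


class TestPartialWarps:
    def test_bending_energy_matrix_rank(self, aligned):
        ref = aligned.consensus_configuration()
        pw = partial_warps(ref, aligned)
        assert pw.principal_warps.shape == (11, 8)  # k - 3 principal warps
        assert np.all(pw.bending_eigenvalues > 0)

    def test_scores_reproduce_tangent_distances(self, aligned):
        ref = aligned.consensus_configuration()
        pw = partial_warps(ref, aligned)
        scores = np.hstack([pw.partial_warp_scores, pw.uniform_scores])
        i, j = 3, 17
        d_scores = np.linalg.norm(scores[i] - scores[j])
        d_tangent = np.linalg.norm(aligned.shapes[i] - aligned.shapes[j])
        assert d_scores == pytest.approx(d_tangent, abs=1e-9)

    def test_matches_brute_force_bending_energy_oracle(self, aligned):
        """Principal-warp scores agree with a projection onto an
        independently assembled bending-energy matrix
        K^-1 - K^-1 P (P' K^-1 P)^-1 P' K^-1."""
        ref = aligned.consensus_configuration()
        k = ref.shape[0]
        d2 = ((ref[:, None] - ref[None, :]) ** 2).sum(axis=2)
        K = np.where(d2 > 0, d2 * np.log(np.where(d2 > 0, d2, 1.0)), 0.0)
        P = np.column_stack([np.ones(k), ref])
        Kinv = np.linalg.inv(K)
        be = Kinv - Kinv @ P @ np.linalg.inv(P.T @ Kinv @ P) @ P.T @ Kinv
        be = (be + be.T) / 2
        evals, evecs = np.linalg.eigh(be)
        pw = partial_warps(ref, aligned)
        np.testing.assert_allclose(np.sort(evals)[3:], np.sort(pw.bending_eigenvalues), atol=1e-8)
        # subspaces spanned by the principal warps agree
        ours = pw.principal_warps
        theirs = evecs[:, np.argsort(evals)[3:]]
        overlap = np.linalg.svd(ours.T @ theirs, compute_uv=False)
        np.testing.assert_allclose(overlap, 1.0, atol=1e-8)


class TestSuperimpositionIndependence:
    def test_grids_agree_across_superimpositions(self, rng):
        """The TPS between two shapes expressed in Procrustes vs
        baseline frames differs only by the similarity transforms
        relating the frames."""
        a = REF + rng.normal(0, 0.3, size=REF.shape)
        b = REF + rng.normal(0, 0.3, size=REF.shape)
        pair = np.stack([a, b])
        # pre-projection aligned shapes: exact similarity images of the inputs
        proc = gpa(pair).preshapes.reshape(2, -1, 2)
        base = baseline_superimpose(pair, (1, 11))

        def similarity(src, dst):
            """Exact similarity mapping src onto dst (same shape in two
            frames)."""
            zs = src[:, 0] + 1j * src[:, 1]
            zd = dst[:, 0] + 1j * dst[:, 1]
            zs_c = zs - zs.mean()
            zd_c = zd - zd.mean()
            scale_rot = (np.conj(zs_c) @ zd_c) / (np.conj(zs_c) @ zs_c)
            shift = zd.mean() - scale_rot * zs.mean()
            return lambda pts: _unpack(scale_rot * (pts[:, 0] + 1j * pts[:, 1]) + shift)

        def _unpack(z):
            return np.column_stack([z.real, z.imag])

        s_ref = similarity(proc[0], base[0])
        s_tgt = similarity(proc[1], base[1])
        warp_proc = tps_fit(proc[0], proc[1])
        warp_base = tps_fit(base[0], base[1])
        probes = proc[0] * 0.8 + rng.normal(0, 0.02, size=REF.shape)
        lhs = tps_warp_points(warp_base, s_ref(probes))
        rhs = s_tgt(tps_warp_points(warp_proc, probes))
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)
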