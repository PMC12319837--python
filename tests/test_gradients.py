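"""Embedding pipeline: thresholding, affinity, diffusion maps, alignment."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group, spearmanr

from axisflux import (
    AnalysisConfig,
    ValidationError,
    affinity_normalized_angle,
    compute_sa_axes,
    diffusion_map,
    procrustes_align,
    row_threshold,
    session_qc,
)
from axisflux.connectivity import CoherenceMatrix
from axisflux.gradients import AlignedAxes


class TestRowThreshold:
    def test_full_density_is_identity(self, rng):
        W = np.abs(rng.standard_normal((6, 6)))
        np.testing.assert_array_equal(row_threshold(W, 1.0), W)

    def test_top_one_selection(self):
        W = np.array([[0.9, 0.2, 0.5, 0.1]] * 4)
        out = row_threshold(W, 0.25)
        expected = np.zeros((4, 4))
        expected[:, 0] = 0.9
        np.testing.assert_array_equal(out, expected)

    def test_ties_keep_lowest_index(self):
        W = np.ones((1, 4))
        out = row_threshold(W, 0.5)
        np.testing.assert_array_equal(out, [[1.0, 1.0, 0.0, 0.0]])

    def test_result_generally_asymmetric(self, rng):
        W = np.abs(rng.standard_normal((20, 20)))
        W = (W + W.T) / 2
        out = row_threshold(W, 0.2)
        assert not np.array_equal(out, out.T)


class TestAffinityNormalizedAngle:
    def test_identical_orthogonal_antiparallel(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
        a = affinity_normalized_angle(X)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.5)
        assert a[0, 3] == pytest.approx(0.0, abs=1e-12)

    def test_zero_row_rejected(self):
        X = np.eye(3)
        X[1] = 0
        with pytest.raises(ValidationError, match="parcel index 1"):
            affinity_normalized_angle(X)


class TestDiffusionMap:
    def _path_affinity(self, n=5):
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1.0
        np.fill_diagonal(A, 1.0)
        return A

    def test_path_graph_first_component_monotone(self):
        emb = diffusion_map(self._path_affinity(), alpha=0.5, n_components=3)
        c0 = emb.components[:, 0]
        assert np.all(np.diff(c0) > 0) or np.all(np.diff(c0) < 0)

    def test_complete_graph_has_no_structure(self):
        A = np.ones((6, 6))
        emb = diffusion_map(A, alpha=0.5, n_components=3)
        np.testing.assert_allclose(emb.eigenvalues, 0.0, atol=1e-10)
        np.testing.assert_allclose(emb.components, 0.0, atol=1e-8)

    def test_eigenvalues_non_increasing_below_one(self, rng):
        A = np.abs(rng.standard_normal((15, 15)))
        A = (A + A.T) / 2
        emb = diffusion_map(A, n_components=10)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)
        assert np.all(emb.eigenvalues < 1)
        assert emb.variance_explained.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_matches_dense_eigensolver_oracle(self, alpha, rng):
        # brute-force oracle: eigendecompose the row-stochastic operator
        # directly with a generic dense solver and rescale identically
        P = 10
        A = np.abs(rng.standard_normal((P, P))) + 0.1
        A = (A + A.T) / 2
        emb = diffusion_map(A, alpha=alpha, diffusion_time=0, n_components=4)
        d = A.sum(1)
        At = A / np.outer(d**alpha, d**alpha)
        M = At / At.sum(1, keepdims=True)
        lam, vec = np.linalg.eig(M)
        order = np.argsort(-lam.real)
        lam, vec = lam.real[order], vec.real[:, order]
        np.testing.assert_allclose(emb.eigenvalues, lam[1:5], atol=1e-8)
        for k in range(4):
            v = vec[:, k + 1] / np.linalg.norm(vec[:, k + 1])
            v = v * lam[k + 1] / (1 - lam[k + 1])
            err = min(
                np.abs(emb.components[:, k] - v).max(),
                np.abs(emb.components[:, k] + v).max(),
            )
            assert err < 1e-8

    def test_disconnected_graph_rejected(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        np.fill_diagonal(A, 1.0)
        with pytest.raises(ValidationError, match="not connected"):
            diffusion_map(A)

    def test_permutation_equivariance(self, rng):
        P = 12
        A = np.abs(rng.standard_normal((P, P))) + 0.1
        A = (A + A.T) / 2
        perm = rng.permutation(P)
        emb = diffusion_map(A, n_components=3)
        emb_p = diffusion_map(A[np.ix_(perm, perm)], n_components=3)
        for k in range(3):
            err = min(
                np.abs(emb_p.components[:, k] - emb.components[perm, k]).max(),
                np.abs(emb_p.components[:, k] + emb.components[perm, k]).max(),
            )
            assert err < 1e-8


class TestProcrustes:
    def test_self_alignment_recovers_centered_reference(self, rng):
        X = rng.standard_normal((30, 4))
        out = procrustes_align(X, X)
        np.testing.assert_allclose(out, X - X.mean(0), atol=1e-10)

    def test_recovers_reference_under_orthogonal_map(self, rng):
        ref = rng.standard_normal((30, 4))
        ref -= ref.mean(0)
        R = special_ortho_group.rvs(4, random_state=1)
        out = procrustes_align(ref @ R, ref)
        np.testing.assert_allclose(out, ref, atol=1e-8)

    def test_alignment_never_increases_distance(self, rng):
        src = rng.standard_normal((20, 3))
        ref = rng.standard_normal((20, 3))
        pre = np.linalg.norm(
            (src - src.mean(0)) - (ref - ref.mean(0))
        )
        post = np.linalg.norm(procrustes_align(src, ref) - (ref - ref.mean(0)))
        assert post <= pre + 1e-12

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError, match="mismatch"):
            procrustes_align(rng.standard_normal((5, 2)), rng.standard_normal((5, 3)))


class TestComputeSaAxes:
    def test_identical_sessions_reproduce_mean_axis(self, pipeline100):
        meta, truth, cov, fcs, _ = pipeline100
        axes = compute_sa_axes([fcs[0]] * 3, meta, AnalysisConfig())
        for s in range(3):
            np.testing.assert_allclose(axes.loadings[:, s], axes.mean_axis, atol=1e-6)
        np.testing.assert_allclose(axes.session_corr, 1.0, atol=1e-9)

    def test_recovers_planted_axis(self, pipeline100):
        meta, truth, cov, fcs, axes = pipeline100
        r = spearmanr(axes.mean_axis, truth.g0).statistic
        assert abs(r) > 0.9

    def test_orientation_invariant_on_every_column(self, pipeline100):
        meta, _, _, _, axes = pipeline100
        dmn = meta.network == "default_mode"
        smn = meta.network == "somatomotor"
        assert axes.mean_axis[dmn].mean() > axes.mean_axis[smn].mean()
        for s in range(axes.n_sessions):
            assert axes.loadings[dmn, s].mean() > axes.loadings[smn, s].mean()

    def test_embedding_sign_invariance(self, pipeline100):
        # negating the session connectome's eigenvector is absorbed by
        # alignment: axes from identical inputs agree regardless of sign
        meta, _, _, fcs, axes = pipeline100
        axes2 = compute_sa_axes(list(fcs), meta, AnalysisConfig())
        np.testing.assert_allclose(axes2.loadings, axes.loadings, atol=1e-8)


class TestSessionQc:
    def _axes(self, loadings, ve=None):
        S = loadings.shape[1]
        mean_axis = loadings.mean(1)
        corr = np.array(
            [spearmanr(loadings[:, s], mean_axis).statistic for s in range(S)]
        )
        return AlignedAxes(
            loadings=loadings,
            mean_axis=mean_axis,
            session_ids=tuple(f"day_{s:02d}" for s in range(1, S + 1)),
            session_corr=corr,
            variance_explained_pc1=ve if ve is not None else np.full(S, 0.3),
        )

    def test_clean_sessions_unflagged(self, rng):
        base = np.sort(rng.standard_normal(50))
        loadings = base[:, None] + 0.01 * rng.standard_normal((50, 6))
        assert session_qc(self._axes(loadings)) == []

    def test_dissimilar_session_flagged(self, rng):
        base = np.sort(rng.standard_normal(50))
        loadings = base[:, None] + 0.01 * rng.standard_normal((50, 6))
        loadings[:, 3] = rng.standard_normal(50)  # unrelated axis
        flags = session_qc(self._axes(loadings), corr_threshold=0.5)
        assert flags == ["day_04"]

    def test_low_variance_explained_flagged(self, rng):
        base = np.sort(rng.standard_normal(50))
        loadings = base[:, None] + 0.01 * rng.standard_normal((50, 8))
        ve = np.full(8, 0.34)
        ve += 0.001 * np.arange(8)  # nonzero MAD
        ve[5] = 0.10
        flags = session_qc(self._axes(loadings, ve), ve_z_threshold=3.0)
        assert flags == ["day_06"]

    def test_impossible_threshold_flags_all(self, rng):
        base = np.sort(rng.standard_normal(50))
        loadings = base[:, None] + 0.01 * rng.standard_normal((50, 4))
        flags = session_qc(self._axes(loadings), corr_threshold=1.01)
        assert len(flags) == 4
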