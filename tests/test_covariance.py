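"""Covariance estimation, CSP, PCA and Riemannian tangent-space geometry."""

import numpy as np
import pytest
from scipy import linalg as sla

from eegdecode import (
    BandCovarianceSet,
    airm_distance,
    apply_filter_bank,
    csp_fit,
    csp_log_features,
    epoch_covariance,
    geodesic_midpoint,
    pca_fit,
    project_covariances,
    riemannian_mean,
    tangent_features,
    tangent_vectorize,
)
from eegdecode.covariance import fit_riemann_references

from conftest import make_epochs, random_spd


def covset_from_mats(mats, labels=None):
    """(epochs, N, N) stack as a single-band covariance set."""
    mats = np.asarray(mats)
    names = [f"c{i}" for i in range(mats.shape[-1])]
    lab = None if labels is None else np.asarray(labels, object)
    return BandCovarianceSet(mats[:, None], ["b"], names, lab)


def csp_oracle(S1, S2, J):
    """Whiten by (S1+S2)^(-1/2), eigendecompose whitened S1, map back."""
    C = S1 + S2
    C_isq = sla.fractional_matrix_power(C, -0.5).real
    lam, V = np.linalg.eigh(C_isq @ S1 @ C_isq)
    order = np.argsort(lam)[::-1][:J]
    return (C_isq @ V)[:, order], lam[order]


class TestEpochCovariance:
    def test_white_noise_recovers_identity(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((500, 4, 250)))
        cov = epoch_covariance(_bands_one(ep), shrinkage=0.0)
        mean = cov.matrices[:, 0].mean(axis=0)
        assert np.allclose(mean, np.eye(4), atol=0.02)

    def test_full_shrinkage_is_scaled_identity(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((3, 4, 100)))
        cov = epoch_covariance(_bands_one(ep), shrinkage=1.0)
        for S in cov.matrices[:, 0]:
            assert np.allclose(S, (np.trace(S) / 4) * np.eye(4), atol=1e-12)

    def test_rank_one_epoch_shrunk_pd(self):
        v = np.linspace(1, 2, 80)
        data = np.outer(np.arange(1, 4.0), v)[None]  # 1 epoch, 3 ch, rank 1
        cov = epoch_covariance(_bands_one(make_epochs(data)), shrinkage=0.05)
        assert np.linalg.eigvalsh(cov.matrices[0, 0]).min() > 0

    def test_nonfinite_input_rejected(self):
        be = _bands_one(make_epochs(np.zeros((2, 3, 50))))
        be.data = be.data.copy()
        be.data[0, 1, 0, 0] = np.nan  # corrupt the band-decomposed signal
        with pytest.raises(ValueError, match="non-finite"):
            epoch_covariance(be)


def _bands_one(ep):
    """Wrap raw epochs as a single identity 'band' (no filtering)."""
    from eegdecode.containers import BandDefinition, BandEpochs

    return BandEpochs(ep.data[None], [BandDefinition("b", 1.0, 2.0)], ep)


class TestCSP:
    def test_equal_class_means_give_half_eigenvalues(self):
        rng = np.random.default_rng(2)
        S = random_spd(rng, 5)
        cov = covset_from_mats([S, S], ["M", "H"])
        f = csp_fit(cov, J=5)
        assert np.allclose(f.eigenvalues[0], 0.5, atol=1e-12)

    def test_two_channel_hand_solution(self):
        """S1=diag(4,1), S2=diag(1,1): top filter is channel 1, lambda=4/5."""
        cov = covset_from_mats([np.diag([4.0, 1.0]), np.diag([1.0, 1.0])], ["M", "H"])
        f = csp_fit(cov, J=1)
        assert f.eigenvalues[0][0] == pytest.approx(0.8, abs=1e-12)
        w = f.filters[0][:, 0]
        assert abs(w[1]) < 1e-12 and abs(w[0]) > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_whitening_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        S1, S2 = random_spd(rng, 8), random_spd(rng, 8)
        cov = covset_from_mats([S1, S2], ["M", "H"])
        f = csp_fit(cov, J=8)
        Wo, lam = csp_oracle(S1, S2, 8)
        assert np.allclose(f.eigenvalues[0], lam, atol=1e-8)
        W = f.filters[0]
        sign = np.sign(np.sum(Wo * W, axis=0))
        assert np.allclose(Wo * sign, W, atol=1e-6)

    def test_variance_ratio_identity_and_sorting(self):
        rng = np.random.default_rng(3)
        S1, S2 = random_spd(rng, 6), random_spd(rng, 6)
        f = csp_fit(covset_from_mats([S1, S2], ["M", "H"]), J=6)
        lam = f.eigenvalues[0]
        assert np.all(np.diff(lam) <= 1e-12)
        for j in range(6):
            w = f.filters[0][:, j]
            assert (w @ S1 @ w) / (w @ (S1 + S2) @ w) == pytest.approx(lam[j], abs=1e-10)

    def test_single_class_and_bad_J(self):
        rng = np.random.default_rng(4)
        cov = covset_from_mats([random_spd(rng, 3)] * 2, ["M", "M"])
        with pytest.raises(ValueError, match="classes"):
            csp_fit(cov, J=2)
        cov2 = covset_from_mats([random_spd(rng, 3)] * 2, ["M", "H"])
        with pytest.raises(ValueError, match="J must"):
            csp_fit(cov2, J=4)


class TestCSPLogFeatures:
    def test_class_mean_epoch_maps_to_zero(self):
        rng = np.random.default_rng(5)
        S1, S2 = random_spd(rng, 4), random_spd(rng, 4)
        f = csp_fit(covset_from_mats([S1, S2], ["M", "H"]), J=3)
        fm = csp_log_features(covset_from_mats([S1]), f)
        assert np.allclose(fm.values, 0.0, atol=1e-12)

    def test_scaling_by_e_gives_unit_feature(self):
        rng = np.random.default_rng(6)
        S1, S2 = random_spd(rng, 4), random_spd(rng, 4)
        f = csp_fit(covset_from_mats([S1, S2], ["M", "H"]), J=2)
        fm = csp_log_features(covset_from_mats([np.e * S1]), f)
        assert np.allclose(fm.values, 1.0, atol=1e-12)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(7)
        S1, S2 = random_spd(rng, 5), random_spd(rng, 5)
        X = random_spd(rng, 5)
        f = csp_fit(covset_from_mats([S1, S2], ["M", "H"]), J=4)
        fm = csp_log_features(covset_from_mats([X]), f)
        W = f.filters[0]
        for j in range(4):
            w = W[:, j]
            expect = np.log(w @ X @ w) - np.log(w @ S1 @ w)
            assert fm.values[0, j] == pytest.approx(expect, abs=1e-10)


class TestPCA:
    def test_diagonal_mean_selects_top_channels(self):
        cov = covset_from_mats([np.diag([3.0, 2.0, 1.0])])
        f = pca_fit(cov, J=2)
        W = np.abs(f.filters[0])
        assert W[0, 0] == pytest.approx(1.0) and W[1, 1] == pytest.approx(1.0)
        assert np.allclose(f.eigenvalues[0], [3.0, 2.0])

    def test_full_basis_orthonormal(self):
        rng = np.random.default_rng(8)
        cov = covset_from_mats([random_spd(rng, 5) for _ in range(4)])
        W = pca_fit(cov, J=5).filters[0]
        assert np.allclose(W.T @ W, np.eye(5), atol=1e-10)

    def test_projected_variance_equals_top_eigenvalues(self):
        rng = np.random.default_rng(9)
        mats = [random_spd(rng, 6) for _ in range(10)]
        cov = covset_from_mats(mats)
        f = pca_fit(cov, J=3)
        proj = project_covariances(cov, f)
        total = np.trace(proj.matrices[:, 0].mean(axis=0))
        assert total == pytest.approx(np.sum(f.eigenvalues[0]), rel=1e-10)


class TestRiemannianMean:
    def test_fixed_point_of_identical_inputs(self):
        rng = np.random.default_rng(10)
        S = random_spd(rng, 4)
        ref = riemannian_mean(np.stack([S] * 5))
        assert np.allclose(ref.mean, S, atol=1e-8)
        assert np.allclose(ref.invsqrt @ ref.mean @ ref.invsqrt, np.eye(4), atol=1e-8)

    def test_two_matrix_mean_is_geodesic_midpoint(self):
        rng = np.random.default_rng(11)
        A, B = random_spd(rng, 4), random_spd(rng, 4)
        ref = riemannian_mean(np.stack([A, B]), tol=1e-10, max_iter=100)
        assert np.allclose(ref.mean, geodesic_midpoint(A, B), atol=1e-6)

    def test_commuting_diagonals_give_geometric_mean(self):
        mats = np.stack([np.diag([1.0, 8.0]), np.diag([4.0, 2.0]), np.diag([2.0, 4.0])])
        ref = riemannian_mean(mats, tol=1e-12, max_iter=200)
        expect = np.diag(np.exp(np.log(np.array([[1, 8], [4, 2], [2, 4.0]])).mean(axis=0)))
        assert np.allclose(ref.mean, expect, atol=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        mats = np.stack([random_spd(rng, 3) for _ in range(6)])
        a = riemannian_mean(mats).mean
        b = riemannian_mean(mats[::-1]).mean
        assert np.allclose(a, b, atol=1e-7)

    def test_nonconvergence_reports_gradient(self):
        rng = np.random.default_rng(13)
        mats = np.stack([random_spd(rng, 3) for _ in range(4)])
        with pytest.raises(RuntimeError, match="gradient norm"):
            riemannian_mean(mats, tol=1e-16, max_iter=1)


class TestTangentSpace:
    def test_reference_maps_to_zero(self):
        rng = np.random.default_rng(14)
        S = random_spd(rng, 3)
        ref = riemannian_mean(np.stack([S] * 2))
        assert np.allclose(tangent_vectorize(S, ref), 0.0, atol=1e-8)

    def test_component_count(self):
        rng = np.random.default_rng(15)
        mats = np.stack([random_spd(rng, 2) for _ in range(4)])
        ref = riemannian_mean(mats)
        v = tangent_vectorize(mats, ref)
        assert v.shape == (4, 3)  # J(J+1)/2 with J=2

    def test_norm_equals_affine_invariant_distance(self):
        rng = np.random.default_rng(16)
        ref = riemannian_mean(np.stack([random_spd(rng, 5) for _ in range(3)]))
        S = random_spd(rng, 5)
        v = tangent_vectorize(S, ref)
        assert np.linalg.norm(v) == pytest.approx(airm_distance(ref.mean, S), abs=1e-8)

    def test_affine_invariance_of_norms(self):
        """Congruence transform of data and mean leaves tangent norms fixed."""
        rng = np.random.default_rng(17)
        mats = np.stack([random_spd(rng, 4) for _ in range(6)])
        G = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        ref = riemannian_mean(mats, tol=1e-10, max_iter=200)
        mats_t = G @ mats @ G.T
        ref_t = riemannian_mean(mats_t, tol=1e-10, max_iter=200)
        n1 = np.linalg.norm(tangent_vectorize(mats, ref), axis=1)
        n2 = np.linalg.norm(tangent_vectorize(mats_t, ref_t), axis=1)
        assert np.allclose(n1, n2, atol=1e-7)

    def test_non_spd_rejected(self):
        rng = np.random.default_rng(18)
        ref = riemannian_mean(np.stack([random_spd(rng, 3)] * 2))
        bad = np.diag([1.0, -1.0, 1.0])
        with pytest.raises(ValueError, match="positive-definite"):
            tangent_vectorize(bad, ref)

    def test_band_concatenated_feature_count(self, tiny_cohort):
        _cfg, epochs, _ = tiny_cohort
        cov = epoch_covariance(apply_filter_bank(epochs))
        filt = pca_fit(cov, J=3)
        proj = project_covariances(cov, filt)
        fm = tangent_features(proj, fit_riemann_references(proj))
        assert fm.values.shape == (epochs.n_epochs, 7 * 6)  # K * J(J+1)/2
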