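"""Variance propagation and bootstrap: formulas, sampler, consistency."""

import numpy as np
import pytest
import scipy.linalg

from mrsidenoise.core import truncated_svd
from mrsidenoise.data import MRSIData
from mrsidenoise.denoise import PatchSpec, denoise_lora, denoise_lp, denoise_st_global, denoise_st_local
from mrsidenoise.phantoms import add_noise, make_singlepeak_phantom
from mrsidenoise.rank_select import ThresholdSpec
from mrsidenoise.uncertainty import (
    BootstrapSpec,
    VoxelCovariance,
    bootstrap_fit,
    covariance_for_voxel,
    entrywise_variance,
    patch_covariance,
    sample_correlated_noise,
    sigma2_from_noise_sd,
    voxel_covariance,
)

from conftest import random_complex


def fixed(rank):
    return ThresholdSpec(mode="fixed_rank", fixed_rank=rank)


class TestEntrywiseVariance:
    def test_sum_identity(self, rng):
        """Row norms of unit-norm-column factors sum to the rank, so the
        variance map sums to sigma2 * rank * (M + N) exactly."""
        f = truncated_svd(random_complex(rng, (12, 8)), 3)
        v = entrywise_variance(f, 0.5)
        assert np.sum(v) == pytest.approx(0.5 * 3 * (12 + 8), rel=1e-10)
        assert np.all(v > 0)

    def test_full_rank_square_mean_is_2sigma2(self, rng):
        f = truncated_svd(random_complex(rng, (6, 6)), 6)
        v = entrywise_variance(f, 1.0)
        assert np.mean(v) == pytest.approx(2.0, rel=1e-10)
        assert np.all(v <= 2.0 + 1e-10)

    def test_soft_factors_rejected(self, rng):
        from mrsidenoise.core import svt

        _, f = svt(random_complex(rng, (6, 6)), 0.5)
        with pytest.raises(ValueError):
            entrywise_variance(f, 1.0)

    def test_invariant_under_degenerate_subspace_rotation(self):
        """With a repeated singular value the SVD basis within the subspace
        is arbitrary; the row norms (hence the variances) are not."""
        rng = np.random.default_rng(5)
        u = scipy.linalg.qr(random_complex(rng, (8, 2)), mode="economic")[0]
        v = scipy.linalg.qr(random_complex(rng, (6, 2)), mode="economic")[0]
        m = 3.0 * u @ v.conj().T  # singular value 3 with multiplicity 2
        # two different orthonormal bases of the same subspace
        q = scipy.linalg.qr(random_complex(rng, (2, 2)))[0]
        f1 = truncated_svd(m, 2)
        f2 = truncated_svd((3.0 * (u @ q) @ (v @ q).conj().T), 2)
        v1 = entrywise_variance(f1, 1.0)
        v2 = entrywise_variance(f2, 1.0)
        assert np.allclose(v1, v2, atol=1e-8)


class TestVoxelCovariance:
    def test_rank_zero_gives_zero(self, rng):
        f = truncated_svd(random_complex(rng, (8, 4)), 0)
        cov = voxel_covariance(f, 0, 1.0)
        assert np.all(cov.cov == 0)

    def test_hermitian_with_entrywise_variance_diagonal(self, rng):
        f = truncated_svd(random_complex(rng, (10, 6)), 2)
        cov = voxel_covariance(f, 3, 0.7)
        assert np.allclose(cov.cov, cov.cov.conj().T, atol=1e-10)
        assert np.allclose(
            cov.variances, entrywise_variance(f, 0.7)[:, 3], atol=1e-12
        )
        # off-diagonals are the U row Gram matrix
        i, j = 1, 4
        expected = 0.7 * np.vdot(f.U_hat[j, :], f.U_hat[i, :])
        assert cov.cov[i, j] == pytest.approx(expected)

    def test_column_out_of_range(self, rng):
        f = truncated_svd(random_complex(rng, (8, 4)), 1)
        with pytest.raises(ValueError):
            voxel_covariance(f, 4, 1.0)

    def test_mc_covariance_structure_matches(self):
        """Leading eigenvector of the predicted covariance aligns with the
        MC cross-moment estimate after global rank-1 ST denoising."""
        truth = make_singlepeak_phantom(n_t=128)
        errs = []
        out0 = None
        for rep in range(50):
            noisy = add_noise(truth, 0.1, seed=700 + rep)
            out = denoise_st_global(noisy, fixed(1))
            out0 = out0 or out
            errs.append(out.data.fid[0, 0, 0])
        errs = np.asarray(errs)
        errs = errs - errs.mean(axis=0)
        mc_cov = errs.T.conj() @ errs / (len(errs) - 1)
        pred = covariance_for_voxel(out0, (0, 0, 0), 0.1).cov
        ev_mc = np.linalg.eigh(mc_cov)[1][:, -1]
        ev_pred = np.linalg.eigh(pred)[1][:, -1]
        cos = abs(np.vdot(ev_mc, ev_pred))
        assert cos > 0.8


class TestPatchCovariance:
    def test_single_patch_equals_voxel_covariance(self):
        truth = make_singlepeak_phantom(n_t=64)
        noisy = add_noise(truth, 0.1, seed=3)
        out = denoise_st_global(noisy, fixed(1))
        sigma2 = sigma2_from_noise_sd(0.1)
        direct = voxel_covariance(out.factors[0].factors, 0, sigma2).cov
        via = patch_covariance(out, (0, 0, 0), sigma2).cov
        assert np.allclose(direct, via, atol=1e-12)

    def test_interior_voxel_is_mean_of_nine_patches(self):
        truth = make_singlepeak_phantom(n_t=64)
        noisy = add_noise(truth, 0.1, seed=4)
        out = denoise_st_local(noisy, fixed(1), PatchSpec(size=(3, 3, 1), stride=1))
        sigma2 = sigma2_from_noise_sd(0.1)
        voxel = (4, 4, 0)
        covering = [
            e for e in out.factors if voxel in e.voxel_index
        ]
        assert len(covering) == 9
        manual = sum(
            voxel_covariance(e.factors, e.voxel_index.index(voxel), sigma2).cov
            for e in covering
        ) / 9
        assert np.allclose(patch_covariance(out, voxel, sigma2).cov, manual, atol=1e-12)

    def test_uncovered_voxel_rejected(self):
        truth = make_singlepeak_phantom(n_t=64)
        noisy = add_noise(truth, 0.1, seed=5)
        out = denoise_st_global(noisy, fixed(1))
        with pytest.raises(ValueError):
            patch_covariance(out, (100, 0, 0), 1.0)

    def test_lp_and_lora_refused(self):
        truth = make_singlepeak_phantom(n_t=64)
        noisy = add_noise(truth, 0.1, seed=6)
        for out in (denoise_lp(noisy, 1), denoise_lora(noisy, fixed(1), lp_rank=1)):
            with pytest.raises(ValueError, match="Hankel"):
                covariance_for_voxel(out, (0, 0, 0), 0.1)


class TestSampler:
    def test_diagonal_cov_gives_independent_marginals(self, rng):
        var = np.array([1.0, 4.0, 0.25])
        cov = VoxelCovariance((0, 0, 0), np.diag(var).astype(complex), 1.0)
        z = sample_correlated_noise(cov, 200_000, seed=8)
        emp = np.mean(np.abs(z) ** 2, axis=0)
        assert np.allclose(emp, var, rtol=0.03)
        # circularity: pseudo-covariance vanishes
        pseudo = np.abs(np.mean(z**2, axis=0))
        assert np.all(pseudo < 0.05 * var)

    def test_rank1_cov_draws_along_eigenvector(self, rng):
        u = random_complex(rng, 4)
        u /= np.linalg.norm(u)
        cov = np.outer(u, u.conj())
        z = sample_correlated_noise(cov, 100, seed=9)
        # every draw is proportional to u
        proj = z - (z @ u.conj())[:, None] * u[None, :]
        assert np.max(np.abs(proj)) < 1e-10

    def test_empirical_covariance_matches_after_clipping(self, rng):
        """An (indefinite) assembled covariance is clipped to PSD; the
        sampler then reproduces the clipped matrix."""
        a = random_complex(rng, (6, 6))
        herm = 0.5 * (a + a.conj().T)  # indefinite Hermitian
        evals, evecs = np.linalg.eigh(herm)
        clipped = (evecs * np.maximum(evals, 0)) @ evecs.conj().T
        z = sample_correlated_noise(herm, 100_000, seed=10)
        emp = z.T @ z.conj() / len(z)
        err = np.linalg.norm(emp - clipped) / np.linalg.norm(clipped)
        assert err < 0.03

    def test_all_negative_cov_rejected(self):
        with pytest.raises(ValueError):
            sample_correlated_noise(-np.eye(3).astype(complex), 10, seed=1)


class TestBootstrapFit:
    def test_zero_cov_gives_zero_sd(self):
        truth = make_singlepeak_phantom(grid_shape=(1, 1, 1), n_t=128)
        cov = VoxelCovariance((0, 0, 0), np.zeros((128, 128), complex), 0.0)
        mean, sd, n = bootstrap_fit(
            truth.fid[0, 0, 0], truth.dwell_time, cov,
            BootstrapSpec(n_reps=5, seed=2),
        )
        assert np.allclose(sd, 0.0, atol=1e-10)
        assert mean[0] == pytest.approx(1.0, abs=1e-6)

    def test_iid_cov_matches_conventional_sd(self):
        """With an i.i.d. covariance (no denoising) the bootstrap SD agrees
        with the conventional Jacobian-derived SD."""
        from mrsidenoise.specfit import fit_voxel

        sd = 0.05
        truth = make_singlepeak_phantom(grid_shape=(1, 1, 1))
        noisy = add_noise(truth, sd, seed=21)
        fid = noisy.fid[0, 0, 0]
        cov = VoxelCovariance(
            (0, 0, 0),
            sigma2_from_noise_sd(sd) * np.eye(truth.n_t, dtype=complex),
            sigma2_from_noise_sd(sd),
        )
        _, boot_sd, _ = bootstrap_fit(
            fid, truth.dwell_time, cov, BootstrapSpec(n_reps=100, seed=3)
        )
        conv = fit_voxel(fid, truth.dwell_time).amplitude_sd()
        assert boot_sd[0] == pytest.approx(conv, rel=0.15)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            BootstrapSpec(n_reps=1)
        with pytest.raises(ValueError):
            BootstrapSpec(psd_repair="fix")
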