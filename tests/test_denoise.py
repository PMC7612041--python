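"""Denoising pipelines: exact recovery, patch combinatorics, residual noise."""

import numpy as np
import pytest

from mrsidenoise.core import HankelLayout
from mrsidenoise.data import MRSIData
from mrsidenoise.denoise import (
    PatchSpec,
    denoise_lora,
    denoise_lp,
    denoise_st_global,
    denoise_st_local,
)
from mrsidenoise.phantoms import (
    PeakParams,
    add_noise,
    make_rank3_phantom,
    make_singlepeak_phantom,
    synthesize_fid,
)
from mrsidenoise.rank_select import ThresholdSpec


def fixed(rank):
    return ThresholdSpec(mode="fixed_rank", fixed_rank=rank)


def rel_err(a, b):
    return np.linalg.norm(a - b) / np.linalg.norm(b)


@pytest.fixture(scope="module")
def rank3():
    return make_rank3_phantom()


@pytest.fixture(scope="module")
def noisy_singlepeak():
    truth = make_singlepeak_phantom()
    return truth, add_noise(truth, 0.1, seed=31)


class TestLP:
    def test_exact_recovery_of_three_exponentials(self):
        peaks = [
            PeakParams(1.0, -20.0, -150.0),
            PeakParams(0.5, -40.0, 10.0),
            PeakParams(0.25, -15.0, 220.0),
        ]
        fid = synthesize_fid(peaks, 128, 1e-3)
        data = MRSIData(fid.reshape(1, 1, 1, -1), 1e-3)
        out = denoise_lp(data, rank=3)
        assert rel_err(out.data.fid, data.fid) < 1e-8

    def test_full_rank_is_identity(self, noisy_singlepeak):
        _, noisy = noisy_singlepeak
        small = MRSIData(noisy.fid[:2, :1, :, :32], noisy.dwell_time)
        layout = HankelLayout.default(32)
        out = denoise_lp(small, rank=min(layout.n_rows, layout.n_cols), layout=layout)
        assert rel_err(out.data.fid, small.fid) < 1e-10

    def test_reduces_baseline_noise(self, noisy_singlepeak):
        """Rank-1 LP denoising leaves less residual noise in the late
        (signal-free) part of the FID than the input noise level."""
        truth, noisy = noisy_singlepeak
        out = denoise_lp(noisy, rank=1)
        resid = out.data.fid[..., 300:] - truth.fid[..., 300:]
        in_resid = noisy.fid[..., 300:] - truth.fid[..., 300:]
        assert np.std(resid.real) < 0.5 * np.std(in_resid.real)

    def test_rank_too_large_rejected(self, rank3):
        with pytest.raises(ValueError):
            denoise_lp(rank3, rank=10_000)

    def test_masked_voxels_untouched(self, noisy_singlepeak):
        _, noisy = noisy_singlepeak
        masked = noisy.copy()
        masked.mask = masked.mask.copy()
        masked.mask[0, 0, 0] = False
        out = denoise_lp(masked, rank=1)
        assert np.array_equal(out.data.fid[0, 0, 0], noisy.fid[0, 0, 0])
        assert not np.array_equal(out.data.fid[1, 0, 0], noisy.fid[1, 0, 0])


class TestSTGlobal:
    def test_exact_recovery_of_rank3_phantom(self, rank3):
        out = denoise_st_global(rank3, fixed(3))
        assert rel_err(out.data.fid, rank3.fid) < 1e-10

    def test_full_rank_is_identity(self, noisy_singlepeak):
        _, noisy = noisy_singlepeak
        out = denoise_st_global(noisy, fixed(noisy.n_masked))
        assert rel_err(out.data.fid, noisy.fid) < 1e-10

    def test_needs_two_voxels(self):
        data = MRSIData(np.ones((1, 1, 1, 8), complex), 1e-3)
        with pytest.raises(ValueError):
            denoise_st_global(data, fixed(1))

    def test_residual_variance_matches_projection_budget(self):
        """After rank-r truncation of an (n_t x n_vox) pure-signal+noise
        Casorati matrix, the residual noise variance per complex entry is
        ~ 2 sigma^2 r (1/n_t + 1/n_vox): the apparent SNR gain of rank
        truncation, which is what makes baseline-derived noise estimates
        misleading."""
        truth = make_singlepeak_phantom()
        sd, rank = 0.1, 1
        errs = []
        for rep in range(50):
            noisy = add_noise(truth, sd, seed=500 + rep)
            out = denoise_st_global(noisy, fixed(rank))
            errs.append(out.data.fid - truth.fid)
        errs = np.asarray(errs)
        mean_var = np.mean(np.abs(errs - errs.mean(axis=0)) ** 2)
        expected = 2 * sd**2 * rank * (1 / truth.n_t + 1 / truth.n_masked)
        assert mean_var == pytest.approx(expected, rel=0.15)

    def test_mc_variance_peaks_with_signal(self):
        """The MC variance of denoised spectra is non-uniform with maxima
        at the signal resonance."""
        truth = make_singlepeak_phantom()
        specs = []
        for rep in range(30):
            noisy = add_noise(truth, 0.1, seed=900 + rep)
            out = denoise_st_global(noisy, fixed(1))
            specs.append(np.fft.fft(out.data.fid, axis=-1))
        specs = np.asarray(specs)
        var = np.var(specs, axis=0).mean(axis=(0, 1, 2))  # per-frequency
        freqs = np.fft.fftfreq(truth.n_t, d=truth.dwell_time)
        on_peak = np.abs(freqs) < 20
        off_peak = np.abs(freqs) > 400
        assert var[on_peak].mean() > 3 * var[off_peak].mean()


class TestSTLocal:
    def test_nonoverlapping_equals_blockwise_global(self, noisy_singlepeak):
        _, noisy = noisy_singlepeak
        patch = PatchSpec(size=(4, 4, 1), stride=4)
        local = denoise_st_local(noisy, fixed(1), patch)
        for ox in (0, 4):
            for oy in (0, 4):
                block = MRSIData(
                    noisy.fid[ox : ox + 4, oy : oy + 4], noisy.dwell_time
                )
                blk = denoise_st_global(block, fixed(1))
                assert np.allclose(
                    local.data.fid[ox : ox + 4, oy : oy + 4], blk.data.fid,
                    atol=1e-12,
                )

    def test_fullgrid_patch_equals_global(self, noisy_singlepeak):
        _, noisy = noisy_singlepeak
        local = denoise_st_local(noisy, fixed(2), PatchSpec(size=(8, 8, 1), stride=1))
        glob = denoise_st_global(noisy, fixed(2))
        assert np.array_equal(local.data.fid, glob.data.fid)

    def test_overlap_counts(self, noisy_singlepeak):
        _, noisy = noisy_singlepeak
        out = denoise_st_local(noisy, fixed(1), PatchSpec(size=(3, 3, 1), stride=1))
        counts = out.overlap_count[:, :, 0]
        assert counts[4, 4] == 9  # interior voxel
        assert counts[0, 0] == 1  # corner
        assert counts[0, 4] == 3  # edge
        assert np.all(counts > 0)

    def test_mp_patchwise_rank_at_most_three(self, rank3):
        noisy = add_noise(rank3, 0.05, seed=77)
        out = denoise_st_local(
            noisy,
            ThresholdSpec(mode="mp", noise_sd=0.05),
            PatchSpec(size=(3, 3, 1), stride=1),
        )
        ranks = [e.threshold.rank for e in out.factors]
        assert all(r <= 3 for r in ranks)
        assert max(ranks) >= 1

    def test_selected_rank_matches_retained_factors(self, rank3):
        """The rank reported by threshold selection equals the number of
        singular triples the denoiser actually kept, for every mode."""
        noisy = add_noise(rank3, 0.05, seed=99)
        for mode in ("mp", "sure_svht", "sure_svt"):
            out = denoise_st_local(
                noisy,
                ThresholdSpec(mode=mode, noise_sd=0.05),
                PatchSpec(size=(4, 4, 1), stride=2),
            )
            for entry in out.factors:
                assert entry.factors.rank == entry.threshold.rank

    def test_patch_larger_than_grid_clipped_with_warning(self, noisy_singlepeak):
        _, noisy = noisy_singlepeak
        with pytest.warns(UserWarning):
            out = denoise_st_local(
                noisy, fixed(1), PatchSpec(size=(16, 16, 1), stride=1)
            )
        glob = denoise_st_global(noisy, fixed(1))
        assert np.array_equal(out.data.fid, glob.data.fid)


class TestLORA:
    def test_exact_recovery_composition(self, rank3):
        out = denoise_lora(rank3, fixed(3), lp_rank=3)
        assert rel_err(out.data.fid, rank3.fid) < 1e-8

    def test_full_lp_rank_equals_st_alone(self, noisy_singlepeak):
        _, noisy = noisy_singlepeak
        small = MRSIData(noisy.fid[:, :, :, :64], noisy.dwell_time)
        layout = HankelLayout.default(64)
        full = min(layout.n_rows, layout.n_cols)
        lora = denoise_lora(small, fixed(1), lp_rank=full, layout=layout)
        st = denoise_st_global(small, fixed(1))
        assert rel_err(lora.data.fid, st.data.fid) < 1e-10

    def test_factor_stages_tagged(self, noisy_singlepeak):
        _, noisy = noisy_singlepeak
        out = denoise_lora(noisy, fixed(1), lp_rank=1)
        stages = {e.stage for e in out.factors}
        assert stages == {"st", "lp"}
        assert out.method == "lora_global"
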