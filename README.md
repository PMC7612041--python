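# mrsi-denoise

Low-rank denoising of magnetic resonance spectroscopic imaging (MRSI)
data with *honest* post-denoising uncertainty estimation.

Low-rank methods — truncating the singular value decomposition of a
Hankel matrix of each voxel's FID (linear-predictability, "LP"
denoising), of the Casorati matrix of the whole grid (spatiotemporal,
"ST" denoising, globally or in overlapping patches), or both in sequence
("LORA") — make spectra *look* dramatically cleaner. But rank truncation
is nonlinear: the residual noise it leaves behind is signal-dependent and
correlated across time points, so the flat baseline of a denoised
spectrum, and the uncertainty a fitting package reports under an i.i.d.
noise assumption, can both be wildly optimistic. This package is for
spectroscopists who want to denoise *and* still quote defensible error
bars on fitted metabolite amplitudes.

## What it provides

* **Denoisers** — LP (Hankel), global ST, patch-wise local ST, and LORA,
  all retaining their truncated SVD factors `(Û, Σ̂, V̂)` for downstream
  uncertainty propagation.
* **Automatic thresholds** — the Marchenko-Pastur noise edge
  (singular-value cut `σ√2(√M + √N)` for per-channel noise SD σ) and
  Stein's unbiased risk estimate (SURE) for both hard (SVHT) and soft
  (SVT) singular-value thresholding.
* **Uncertainty propagation** — the first-order entry-wise variance of a
  hard-truncated matrix,

      var[i, j] = σ² (‖Û[i, :]‖² + ‖V̂[j, :]‖²),

  the per-voxel time×time covariance (off-diagonals
  `σ² ⟨Û[i, :], Û[i′, :]⟩`), and a correlated-noise bootstrap that refits
  perturbed data to give amplitude uncertainties that track the true
  (Monte-Carlo) ones.
* **Peak fitting** — statsmodels-style `PeakModel.fit()` →
  `PeakFitResult` for damped-exponential (Lorentzian) models, with the
  conventional Jacobian-derived covariance for comparison.
* **Built-in phantoms and Monte-Carlo studies** — a uniform single-peak
  grid and an exactly-rank-3 three-peak grid, with fully seeded study
  runners that reproduce the uncertainty and threshold-selection-bias
  analyses.
* **I/O and CLI** — NIfTI-MRS-style complex 4-D NIfTI (dwell time in
  `pixdim[4]`, JSON header extension) plus an `.npz` fallback, and a
  `mrsi-denoise` command with `simulate`, `denoise`, `fit`,
  `uncertainty` and `mc-study` subcommands.

## Worked example

Denoise a noisy single-peak grid (64 identical unit-amplitude 10 Hz
Lorentzians, per-channel noise SD 0.1) by global rank-1 ST truncation and
compare three uncertainty estimates for one voxel's fitted amplitude:

```python
import numpy as np
from mrsidenoise import (
    make_singlepeak_phantom, add_noise, denoise_st_global, ThresholdSpec,
    fit_voxel, covariance_for_voxel, bootstrap_fit, BootstrapSpec,
)

truth = make_singlepeak_phantom()          # 8x8x1 grid, 512 points, 2 kHz
noisy = add_noise(truth, noise_sd=0.1, seed=7)

out = denoise_st_global(noisy, ThresholdSpec(mode="fixed_rank", fixed_rank=1))

fit = fit_voxel(out.data.fid[4, 4, 0], truth.dwell_time)
print(f"amplitude estimate        : {fit.amplitude():.4f}")
print(f"conventional (fit) SD     : {fit.amplitude_sd():.5f}")

cov = covariance_for_voxel(out, (4, 4, 0), noise_sd=0.1)
mean, sd, n_used = bootstrap_fit(
    out.data.fid[4, 4, 0], truth.dwell_time, cov,
    BootstrapSpec(n_reps=100, seed=11),
)
print(f"bootstrap amplitude SD    : {sd[0]:.5f}  ({n_used} replicates)")

noisy_fit = fit_voxel(noisy.fid[4, 4, 0], truth.dwell_time)
print(f"noisy-data conventional SD: {noisy_fit.amplitude_sd():.5f}")
```

Output:

```
amplitude estimate        : 0.9952
conventional (fit) SD     : 0.00317
bootstrap amplitude SD    : 0.01731  (100 replicates)
noisy-data conventional SD: 0.02393
```

Read: before denoising the fit's own error bar (0.0239) is trustworthy.
After global ST denoising the fit reports 0.0032 — an apparent 7.5x
improvement that is an artefact of the shared low-rank subspace (it is
the uncertainty of the *spatial average* of all 64 voxels, 0.0239/8).
The bootstrap estimate, built from the propagated covariance of the
denoised data, reports 0.0173: denoising did genuinely help (about a
1.4x reduction, consistent with Monte-Carlo ground truth), just far less
than the baseline suggests.

The full Monte-Carlo studies behind such statements run from the CLI:

```sh
mrsi-denoise mc-study --preset singlepeak --n-mc 50 --seed 1 --out study.tsv
mrsi-denoise mc-study --preset rank3      --n-mc 50 --seed 1 --out rank3.tsv
```

## Documentation

`docs/methods.md` describes the models, conventions (noise SD is always
per real/imaginary channel), threshold formulas, the validity limits of
the variance propagation (it is refused for LP/LORA output, whose Hankel
lifting breaks its assumptions), and the study designs.
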