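# Methods

This note records the models, conventions and design choices behind
`mrsidenoise`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the approximations live.

## Signal and noise model

Each voxel of an MRSI acquisition carries a complex free induction decay
(FID) sampled every `t_s` seconds (the dwell time). The synthetic signal
model is a sum of damped complex exponentials (Lorentzian resonances)

    x[n] = sum_k c_k exp((alpha_k + 2*pi*i*omega_k) n t_s) exp(i*phi_k)

with amplitude `c_k` (arbitrary units), damping `alpha_k <= 0` in s^-1
(absorption-mode linewidth fwhm = -alpha_k/pi Hz), frequency offset
`omega_k` in Hz and phase `phi_k` in radians. Acquisition noise is i.i.d.
circular complex Gaussian.

**Noise convention.** `noise_sd` always denotes the standard deviation of
each of the real and imaginary channels separately, so one complex sample
has total variance `2 * noise_sd**2`. Everything downstream (the MP edge,
the variance-propagation formulas, the noise estimator) keeps this
convention; functions that need the *per-entry complex* variance
(`sigma2 = 2 * noise_sd**2`) say so explicitly and
`uncertainty.sigma2_from_noise_sd` performs the conversion. This makes the
propagated variances directly comparable to Monte-Carlo moments of the
complex data.

## Low-rank denoising

All four pipelines reduce to singular-value truncation or shrinkage of a
matrix lifting of the data:

* **LP (linear predictability)** lifts each voxel's FID into a Hankel
  matrix `H[i, j] = s[i + j]` of shape `(M - K + 1) x K`, truncates it to a
  fixed rank, and reads the signal back from the first row and last column
  of the truncated matrix. No re-Hankelization (Cadzow-style alternating
  projection) is performed; the edge read-back deliberately "softens" the
  filter. The column count `K` defaults to `floor(M/2) + 1` — a
  near-square lifting maximizes the usable rank budget, the common choice
  in the linear-prediction literature.
* **ST (spatiotemporal)** forms the Casorati matrix (time x masked voxels,
  columns in row-major voxel order, recorded in a `voxel_index`) and
  truncates or shrinks it, globally or patch-wise.
* **LORA** runs ST first, then LP voxel-wise (default LP rank 20, a
  heuristic upper bound on the number of resolvable spectral components).

**Patch enumeration.** Local ST uses patches of a given 3-D size anchored
at stride-lattice origins and enumerated fully inside the grid; the final
origin along each axis is clamped to `grid - size` so the far edge is
always covered, and a patch larger than the grid is clipped (with a
warning). Estimates from overlapping patches are averaged with uniform
weights. With this enumeration, a full-grid patch reproduces global ST
exactly and `stride == size` reproduces independent block-wise ST; on an
8x8 grid with 3x3 patches and stride 1, interior voxels are covered by 9
patches and corners by 1. Patches with fewer than 2 masked voxels are
skipped (a Casorati matrix needs at least two columns). Noise is assumed
spatially stationary, so one grid-level noise SD serves every patch.

**Thresholding.** Hard thresholding retains singular values strictly above
the cut (a value exactly at the threshold is discarded — the conservative
Heaviside convention `H(0) = 0`); soft thresholding (SVT) shrinks to
`(sigma_i - lambda)_+` and stores the shrunk values in the factors.

**SVD backends.** Threshold-selection paths always use the full LAPACK
SVD (they need the entire spectrum, and the full decomposition is
bit-reproducible). Fixed-rank truncation of large matrices at tiny rank
(the voxel-wise Hankel stage, rank <= 4) uses a Lanczos solver with a
fixed (non-random) start vector: also deterministic, and several times
faster at these shapes. Singular values below `1e-12 * sigma_1` are
treated as numerically zero.

## Automatic threshold selection

* **Marchenko-Pastur (MP).** For an `m x n` pure-noise matrix the largest
  eigenvalue of `(1/n) E E†` converges to `tau^2 (1 + sqrt(gamma))^2` with
  `gamma = m/n <= 1` and `tau^2` the per-entry complex variance. The
  singular-value cut is therefore
  `noise_sd * sqrt(2) * (sqrt(m) + sqrt(n))`; everything at or below it is
  zeroed. The radical form of the edge is used (the `(1 + gamma)^2` form
  sometimes seen in print is a typographical loss of the square root; only
  the radical form reproduces the false-positive behaviour of the edge,
  which is how this implementation validates its normalization — a
  pure-noise 512 x 64 matrix selects rank <= 1 in >= 95% of trials).
* **SURE for SVT.** Stein's unbiased risk estimate of
  `E || M0 - SVT_lambda(M) ||_F^2` for complex data,
  `SURE = -mn tau^2 + sum_i min(sigma_i, lambda)^2 + tau^2 * div`, with the
  divergence of the spectral map over the `2mn` real coordinates

      div = sum_i [ 1(s_i > lambda) + (2|m - n| + 1)(s_i - lambda)_+ / s_i ]
            + 4 sum_{i != j} s_i (s_i - lambda)_+ / (s_i^2 - s_j^2).

  (Sanity anchor: at `lambda = 0` the divergence is exactly `2mn` and the
  risk estimate equals the total noise energy `mn tau^2`.) The minimizer
  is found on a grid of 200 log-spaced thresholds spanning
  `[0.1 * noise_sd, sigma_1]`; the SVT risk is smooth in `lambda`, so this
  density is ample. Degenerate `sigma_i = sigma_j` denominators are
  guarded by a `1e-12` regularizer.
* **SURE for SVHT.** The analogous estimate for hard thresholding,
  evaluated only at the midpoints between consecutive singular values (the
  risk is piecewise constant in `lambda`, one candidate per retained
  rank). The hard-threshold divergence ignores the Heaviside jump, so the
  estimate is unbiased only where no singular-value mass sits at the
  threshold — exactly the candidates considered. Monte-Carlo checks
  confirm unbiasedness at gap thresholds and a visible bias for thresholds
  inside the noise bulk, which is why the unbiasedness test evaluates gap
  thresholds for SVHT and the full grid for SVT.

**Noise estimation.** When the noise SD is unknown it is estimated from
the trailing half of the singular-value spectrum: the median of the
trailing half sits at the 0.25 quantile of the Marchenko-Pastur
singular-value distribution of a pure-noise matrix of the same shape, so
`sd_hat = median(trailing half) / sqrt(2 * n * x_0.25(gamma))` with the MP
eigenvalue quantile obtained by numerical integration of the density. A
small number of signal components perturbs only the leading values and
leaves the estimator nearly unbiased (within ~10% on pure noise, ~15%
with a strong rank-1 signal, by simulation).

## Variance propagation after truncation

Rank truncation is nonlinear: the residual noise in "denoised" data is
signal-dependent and correlated. To first order in the noise, a
hard-truncated matrix with factors `(U, S, V)` from data with i.i.d.
complex noise of per-entry variance `sigma2` has entry-wise variance

    var[i, j] = sigma2 (||U[i, :]||^2 + ||V[j, :]||^2)

and, within one Casorati column (voxel), time-time covariance
`cov[i, i'] = sigma2 <U[i, :], U[i', :]>` for `i != i'`, assembled with the
entry-wise variance on the diagonal. Useful identities: the variance map
sums exactly to `sigma2 * rank * (M + N)` (unit-norm factor columns), and
its mean is the "apparent SNR gain"
`sigma2 * rank * (1/M + 1/N)` — the reason residual-baseline SNR
flatters every low-rank method. The formulas are basis-independent within
degenerate singular subspaces (row norms and row Gram matrices are
subspace invariants), which the tests exercise with repeated singular
values.

Scope and caveats:

* The propagation requires the noise to enter the factorized matrix
  i.i.d. — true for the Casorati matrix, false after a Hankel lifting
  (each noise sample appears on a whole anti-diagonal). Covariance
  estimation is therefore *refused* for LP and LORA output.
* It is a moderate-to-high-SNR approximation and degrades with the
  condition number of the signal part.
* For patch-wise denoising, the covariance of a voxel is the arithmetic
  mean over all patches containing it; cross-patch covariance terms are
  not modelled. The off-diagonal structure is captured better than its
  magnitude.
* Because the diagonal (which includes the `||V[j, :]||^2` term) is not
  consistent with the off-diagonal Gram structure, the assembled matrix
  can be slightly indefinite. Before sampling, negative eigenvalues are
  clipped to zero — the minimal Frobenius-norm projection onto the PSD
  cone; no attempt is made to preserve the total variance under clipping.

## Bootstrap uncertainty of fitted amplitudes

Propagating a full covariance through a nonlinear least-squares fit
analytically is impractical, so the package bootstraps: each replicate
adds a fresh circular complex Gaussian draw with the estimated covariance
(`E[z z†] = cov`, `E[z zᵀ] = 0`) to the denoised FID and refits the peak
model; the parameter SD across replicates is the bootstrap uncertainty.
The perturbation is added once, not re-denoised — a first-order
approximation to the sampling distribution of the denoised estimate.
Replicates that fail to converge are dropped and counted; more than 20%
failures aborts with a diagnostic (the threshold is a package decision).
Default 40 replicates; the single-peak studies use up to 100.

The noise SD fed into the covariance comes from the simulation ground
truth when known, otherwise from the trailing-singular-value estimator on
the *pre-denoising* data — never from the denoised baseline, whose
flatness is precisely the artefact being corrected for.

## Spectral fitting and "conventional" uncertainty

Fitting is time-domain nonlinear least squares of the damped-exponential
model, with the complex residual stacked as concatenated real and
imaginary parts. `PeakModel.fit()` uses Levenberg-Marquardt (unbounded)
or trust-region-reflective (bounded) with an analytic Jacobian. The
conventional parameter covariance is `s^2 (J^T J)^{-1}` with
`s^2 = RSS / (n_obs - n_params)`, `n_obs = 2 n_t` — the convention of
standard curve-fitting tools, which implicitly assumes uniform
uncorrelated noise. Default starting values are peak-picked from the
magnitude spectrum with a 10 Hz linewidth guess and zero phase. The
bounded three-peak configuration starts at the known offsets with bounds:
amplitude in `[0, 10 x spectral-height scale]`, frequency within +-50 Hz
of its start, damping in `[-200 pi, 0]`, phase in `[-pi, pi]`.

## Simulation studies

**Single-peak study.** An 8 x 8 x 1 grid of identical unit-amplitude
10 Hz on-resonance Lorentzians (`c = 1`, `alpha = -10 pi`, `omega = 0`,
`phi = 0`); per-channel noise SDs {0.5, 0.1, 0.05, 0.01, 0.005, 0.001};
all denoisers run at the true rank 1. Reported per method and level, as
ratios to the noisy data's Monte-Carlo amplitude SD: the actual (MC) SD,
the mean fit-reported SD, and the mean bootstrap SD. The defaults
`n_t = 512`, `t_s = 1/2000 s` place the acquisition in a realistic MRSI
regime (1 kHz of bandwidth comfortably covering the phantom offsets).

**Rank-3 study.** An 8 x 8 x 1 grid of three-peak voxels at -200, 0 and
+300 Hz with constant phase and linewidth and three smooth, linearly
independent, non-negative concentration maps (linear gradient, centred
Gaussian, off-centre Gaussian; peak amplitude 1), so the noiseless
Casorati matrix has rank exactly 3 by construction. Denoising is local ST
(3 x 3 x 1 patches, stride 1) under five threshold-selection schemes: MP,
fixed rank 2, fixed rank 3, SURE-SVHT and SURE-SVT. Per-channel noise SDs
default to the factor-2 ladder {1.0, 0.5, 0.25, 0.12, 0.06, 0.03}: the
top of the range is chosen so that automatic (MP/SURE) selection
underestimates the true rank — the low-SNR regime where thresholding bias
appears — while the bottom recovers rank 3; this calibration is part of
the study design, verified by inspecting the selected ranks per level.

A caveat on soft thresholding in this geometry: once the noise is high
enough that MP underestimates the rank of a 3 x 3-patch Casorati matrix,
the MSE-optimal soft threshold is comparable to the signal singular
values themselves, so SVT's uniform shrinkage biases fitted amplitudes
down substantially. In these study conditions hard thresholding therefore
retains a concentration-RMSE advantage over soft thresholding even at the
highest noise; soft thresholding's advantage regime (signal components
far above the threshold while hard selection still discards some) is not
reachable in this phantom geometry. Scores: spectral RMSE (root
mean square of `|s - s_hat|` over all masked voxel-time samples),
concentration RMSE (RMS error pooled over peaks, voxels and repetitions),
and the mean/SD/adjusted-Fisher-Pearson-skewness of the signed
concentration errors.

Both studies spawn one independent child stream per repetition from a
single master seed, so any subset is reproducible and the whole study is
bit-identical under a fixed seed.

**Problem sizes.** The shipped test suite and the acceptance script run
the studies at reduced repetition counts (tens rather than hundreds of
repetitions, bootstrap on a subsample of voxels and repetitions) chosen
so each comparison retains a clear margin over its Monte-Carlo error;
full-scale runs are a parameter change.

## What the phantoms do and do not show

The generators emulate the rank structure, noise statistics and
fitting-interaction effects that the denoisers are sensitive to; they do
not emulate realistic metabolite spectra (multiplets, baselines,
macromolecules, Voigt line shapes), scanner artefacts (frequency drift,
phase errors, coil combination residuals) or physiological variability.
Conclusions supported by the passing studies are therefore about the
statistical behaviour of the denoising and uncertainty machinery —
uncertainty ratios, threshold-selection bias, the invalidity of
baseline-derived noise estimates after denoising — not about absolute
performance on in vivo data.

## Known limitations

* Entry-wise variance propagation is first-order and signal-level
  dependent; its off-diagonal covariance captures structure better than
  magnitude, and no correction factor is applied.
* No uncertainty propagation for LP/LORA output (see above) — by design.
* Optimal singular-value shrinkage (beyond hard/soft thresholding) is out
  of scope.
* The patch-mean covariance rule ignores cross-patch terms.
* Patch size and stride are user choices; nothing selects them
  automatically.
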