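"""Post-denoising uncertainty: variance propagation and bootstrap fitting.

Rank truncation is a nonlinear operation, so the residual noise in
"denoised" data is neither uniform nor independent: its variance is
signal-dependent and neighbouring time points are correlated. A
first-order perturbation analysis of the truncated SVD gives, for a
hard-truncated matrix with factors ``(U, S, V)`` and i.i.d. input noise of
per-entry variance ``sigma2``, the entry-wise variance

    var[i, j] = sigma2 * (||U[i, :]||^2 + ||V[j, :]||^2)

and, within one Casorati column (voxel) ``j``, the time-time covariance

    cov[i, i'] = sigma2 * <U[i, :], U[i', :]>      (i != i')

assembled with the entry-wise variance on the diagonal. For patch-wise
denoising the covariance of a voxel is the arithmetic mean over all
patches containing it.

``sigma2`` throughout this module is the variance of one complex entry of
the input noise, ``E|e|^2 = 2 * noise_sd**2`` for per-channel SD
``noise_sd``; the propagated quantities are then directly comparable to
Monte-Carlo moments of the complex data (``use sigma2_from_noise_sd`` to
convert). The propagation is only valid for noise that enters the
factorized matrix i.i.d., which holds for spatiotemporal (Casorati)
denoising but *not* for Hankel-lifted (LP) denoising or the second stage
of LORA — those are refused explicitly.

Because the assembled covariance mixes two first-order approximations it
can be slightly indefinite; before sampling, negative eigenvalues are
clipped to zero (the minimal Frobenius-norm PSD projection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LowRankFactors
from .data import MRSIData
from .denoise import DenoiseOutput, FactorEntry

__all__ = [
    "VoxelCovariance",
    "BootstrapSpec",
    "sigma2_from_noise_sd",
    "entrywise_variance",
    "voxel_covariance",
    "patch_covariance",
    "covariance_for_voxel",
    "sample_correlated_noise",
    "bootstrap_fit",
]


def sigma2_from_noise_sd(noise_sd: float) -> float:
    """Per-entry complex noise variance from the per-channel SD."""
    return 2.0 * float(noise_sd) ** 2


@dataclass
class VoxelCovariance:
    """Time-time complex covariance of one voxel's denoised FID.

    ``cov`` approximates ``E[z z†]`` of the residual noise vector ``z``;
    it is Hermitian with a real non-negative diagonal equal to the
    entry-wise variances.
    """

    voxel: tuple[int, int, int]
    cov: np.ndarray  # (n_t, n_t) complex Hermitian
    source_sigma2: float

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=complex)
        if self.cov.ndim != 2 or self.cov.shape[0] != self.cov.shape[1]:
            raise ValueError("cov must be square")

    @property
    def variances(self) -> np.ndarray:
        return self.cov.diagonal().real


@dataclass(frozen=True)
class BootstrapSpec:
    """Configuration of the correlated-noise bootstrap."""

    n_reps: int = 40
    seed: int = 0
    psd_repair: str = "clip"  # "clip" | "none"
    max_drop_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.psd_repair not in ("clip", "none"):
            raise ValueError("psd_repair must be 'clip' or 'none'")


def _require_hard(factors: LowRankFactors) -> None:
    if factors.shrinkage != "hard":
        raise ValueError(
            "variance propagation assumes hard-truncated factors; "
            "soft-shrunk singular values change the perturbation expansion"
        )


def entrywise_variance(factors: LowRankFactors, sigma2: float) -> np.ndarray:
    """First-order variance of every entry of the truncated reconstruction.

    Returns an ``(M, N)`` real array; entries lie in ``(0, 2 * sigma2]``
    and sum to ``sigma2 * rank * (M + N)`` exactly (columns of the factors
    are unit-norm).
    """
    _require_hard(factors)
    u_row = np.sum(np.abs(factors.U_hat) ** 2, axis=1)  # (M,)
    v_row = np.sum(np.abs(factors.V_hat) ** 2, axis=1)  # (N,)
    return sigma2 * (u_row[:, None] + v_row[None, :])


def voxel_covariance(
    factors: LowRankFactors,
    voxel_col: int,
    sigma2: float,
    voxel: tuple[int, int, int] = (0, 0, 0),
) -> VoxelCovariance:
    """Time-time covariance of one Casorati column after hard truncation.

    Off-diagonal entries are the conjugate inner products of rows of the
    left singular vectors scaled by ``sigma2``; the diagonal carries the
    entry-wise variances (which include the right-singular-vector term).
    """
    _require_hard(factors)
    n_vox = factors.V_hat.shape[0]
    if not 0 <= voxel_col < n_vox:
        raise ValueError(f"voxel column {voxel_col} out of range [0, {n_vox})")
    u = factors.U_hat
    if factors.rank == 0:
        cov = np.zeros((u.shape[0], u.shape[0]), dtype=complex)
        return VoxelCovariance(voxel=voxel, cov=cov, source_sigma2=sigma2)
    cov = sigma2 * (u @ u.conj().T)
    var = entrywise_variance(factors, sigma2)[:, voxel_col]
    np.fill_diagonal(cov, var)
    return VoxelCovariance(voxel=voxel, cov=cov, source_sigma2=sigma2)


def patch_covariance(
    output: DenoiseOutput, voxel: tuple[int, int, int], sigma2: float
) -> VoxelCovariance:
    """Mean covariance over every patch containing ``voxel``."""
    voxel = tuple(int(c) for c in voxel)
    acc = None
    n_found = 0
    for entry in output.st_factor_entries():
        if voxel not in entry.voxel_index:
            continue
        col = entry.voxel_index.index(voxel)
        cov = voxel_covariance(entry.factors, col, sigma2, voxel).cov
        acc = cov if acc is None else acc + cov
        n_found += 1
    if n_found == 0:
        raise ValueError(f"voxel {voxel} is not covered by any factor entry")
    return VoxelCovariance(voxel=voxel, cov=acc / n_found, source_sigma2=sigma2)


def covariance_for_voxel(
    output: DenoiseOutput, voxel: tuple[int, int, int], noise_sd: float | None = None
) -> VoxelCovariance:
    """Closed-form covariance of one voxel of a spatiotemporally denoised grid.

    Works for global and patch-wise ST output; refuses LP and LORA output,
    whose Hankel lifting violates the i.i.d.-input assumption of the
    propagation formulas.
    """
    if output.method not in ("st_global", "st_local"):
        raise ValueError(
            f"variance propagation is not available for method "
            f"{output.method!r}: the Hankel lifting of LP denoising (and the "
            "second stage of LORA) breaks the i.i.d.-noise assumption"
        )
    if noise_sd is None:
        noise_sd = output.noise_sd
    if noise_sd is None:
        raise ValueError("noise SD unknown; pass noise_sd explicitly")
    sigma2 = sigma2_from_noise_sd(noise_sd)
    return patch_covariance(output, voxel, sigma2)


def _psd_clip(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with negative eigenvalues clipped to zero."""
    herm = 0.5 * (cov + cov.conj().T)
    evals, evecs = np.linalg.eigh(herm)
    floor = 1e-14 * max(float(evals[-1]), 0.0)
    evals = np.where(evals > floor, evals, 0.0)
    return evals, evecs


def sample_correlated_noise(
    cov: VoxelCovariance | np.ndarray,
    n: int,
    seed: int | np.random.SeedSequence,
    psd_repair: str = "clip",
) -> np.ndarray:
    """Draw circular complex Gaussian vectors with ``E[z z†] = cov``.

    The matrix is projected to the PSD cone by eigenvalue clipping first
    (unless ``psd_repair='none'``, which raises on indefinite input).
    Returns an ``(n, n_t)`` array with ``E[z zᵀ] = 0`` (circularity).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    c = cov.cov if isinstance(cov, VoxelCovariance) else np.asarray(cov, dtype=complex)
    evals, evecs = _psd_clip(c)
    if psd_repair == "none":
        raw = np.linalg.eigvalsh(0.5 * (c + c.conj().T))
        if np.any(raw < -1e-12 * max(raw.max(), 1e-300)):
            raise ValueError("covariance is indefinite and psd_repair='none'")
    if np.all(evals == 0) and np.any(c != 0):
        raise ValueError("covariance has no non-negative spectrum to sample")
    rng = np.random.default_rng(seed)
    n_t = c.shape[0]
    w = (rng.standard_normal((n, n_t)) + 1j * rng.standard_normal((n, n_t))) / np.sqrt(2.0)
    # rows are z^T with z = Q diag(sqrt(lambda)) w, so E[z z†] = Q Lambda Q†
    return (w * np.sqrt(evals)) @ evecs.T


def bootstrap_fit(
    fid: np.ndarray,
    dwell_time: float,
    cov: VoxelCovariance,
    spec: BootstrapSpec,
    n_peaks: int = 1,
    start=None,
    bounds=None,
    algorithm: str = "lm",
    model_factory=None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Repeatedly refit a voxel perturbed with correlated noise.

    Each replicate adds a fresh draw from the estimated covariance to the
    (denoised) data and refits the peak model; the perturbation is added
    once, not re-denoised, a first-order approximation to the sampling
    distribution of the denoised estimate. Returns ``(mean, sd, n_used)``
    over the flat parameter vector of the converged replicates.

    Raises if the point fit on the unperturbed data fails or if more than
    ``spec.max_drop_fraction`` of replicates fail to converge.
    """
    from .specfit import PeakModel

    def make_model(y):
        if model_factory is not None:
            return model_factory(y, dwell_time)
        return PeakModel(y, dwell_time, n_peaks, start, bounds)

    point = make_model(fid).fit(algorithm)
    if not point.converged:
        raise ValueError("point fit on unperturbed data did not converge")
    noise = sample_correlated_noise(
        cov, spec.n_reps, np.random.SeedSequence(spec.seed), spec.psd_repair
    )
    thetas = []
    n_failed = 0
    for r in range(spec.n_reps):
        res = make_model(np.asarray(fid) + noise[r]).fit(algorithm)
        if res.converged:
            thetas.append(res.theta)
        else:
            n_failed += 1
    if n_failed > spec.max_drop_fraction * spec.n_reps:
        raise ValueError(
            f"bootstrap unstable: {n_failed}/{spec.n_reps} replicates "
            "failed to converge"
        )
    arr = np.array(thetas)
    return arr.mean(axis=0), arr.std(axis=0, ddof=1), arr.shape[0]
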