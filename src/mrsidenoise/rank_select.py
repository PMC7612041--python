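"""Automatic singular-value threshold selection.

Three data-driven rules for choosing how many singular values of a noisy
matrix to keep (or how much to shrink them), plus a fixed-rank passthrough:

* **MP** — the upper edge of the Marchenko-Pastur distribution of a
  pure-noise matrix; every singular value at or below the edge is zeroed
  (hard thresholding).
* **SURE-SVT** — Stein's unbiased risk estimate of the Frobenius MSE of the
  soft-thresholding (singular value shrinkage) estimator, minimized over a
  threshold grid.
* **SURE-SVHT** — the analogous unbiased risk estimate for hard
  thresholding, minimized over the (piecewise-constant) candidate
  thresholds midway between consecutive singular values.

Conventions: matrices are complex with i.i.d. circular Gaussian noise;
``noise_sd`` is the per-channel (real or imaginary) standard deviation, so
each complex entry has total noise variance ``2 * noise_sd**2``. The MP
eigenvalue edge ``tau^2 * (1 + sqrt(gamma))^2`` (``gamma = m/n`` with
``m <= n`` enforced by transposition, ``tau^2`` the per-entry complex
variance) converts to the singular-value cut

    sigma_cut = noise_sd * sqrt(2) * (sqrt(m) + sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "ThresholdSpec",
    "ThresholdResult",
    "mp_threshold",
    "sure_svt",
    "sure_svht",
    "estimate_noise_sd",
]

_EPS = 1e-12  # guards sigma_i == sigma_j degeneracies in divergence terms


@dataclass(frozen=True)
class ThresholdSpec:
    """How the singular-value cut is chosen and applied.

    ``mode`` is one of ``fixed_rank``, ``mp``, ``sure_svt``, ``sure_svht``.
    ``sure_svt`` applies soft shrinkage; all other modes truncate (hard).
    ``noise_sd`` may be a number, ``"estimate"`` (estimate from the matrix)
    or ``None`` (required to be irrelevant, i.e. ``fixed_rank``).
    """

    mode: str = "mp"
    fixed_rank: int | None = None
    noise_sd: float | str | None = "estimate"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_rank", "mp", "sure_svt", "sure_svht"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed_rank" and self.fixed_rank is None:
            raise ValueError("fixed_rank mode requires fixed_rank")

    @property
    def shrinkage(self) -> str:
        return "soft" if self.mode == "sure_svt" else "hard"


@dataclass
class ThresholdResult:
    """Selected threshold ``lam`` and the implied retained rank."""

    lam: float
    rank: int
    risk_curve: list[tuple[float, float]] | None = None


def mp_threshold(
    singular_values: np.ndarray, shape: tuple[int, int], noise_sd: float
) -> ThresholdResult:
    """Marchenko-Pastur singular-value cut for a pure-noise matrix.

    All singular values at or below the cut are discarded (strict-greater
    retention), so on pure noise the selected rank is 0 or occasionally 1.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    s = np.asarray(singular_values, dtype=float)
    m, n = shape
    cut = noise_sd * np.sqrt(2.0) * (np.sqrt(m) + np.sqrt(n))
    return ThresholdResult(lam=float(cut), rank=int(np.sum(s > cut)))


def _sure_svt_value(
    s: np.ndarray, shape: tuple[int, int], tau2: float, lam: float
) -> float:
    """Complex-data SURE of the soft-thresholding estimator at ``lam``.

    ``tau2`` is the total complex noise variance per entry. The divergence
    of the spectral map ``sigma -> (sigma - lam)_+`` over the 2mn real
    coordinates of a complex matrix is

        sum_i [ 1(s_i > lam) + (2|m-n| + 1) (s_i - lam)_+ / s_i ]
        + 4 sum_{i != j} s_i (s_i - lam)_+ / (s_i^2 - s_j^2)
    """
    m, n = shape
    p = min(m, n)
    s = s[:p]
    kept = s > lam
    shrunk = np.where(kept, s - lam, 0.0)
    residual = float(np.sum(np.minimum(s, lam) ** 2))

    div = float(np.sum(kept))
    safe_s = np.where(s > _EPS, s, _EPS)
    div += (2 * abs(m - n) + 1) * float(np.sum(shrunk / safe_s))
    s2 = s**2
    denom = s2[:, None] - s2[None, :]
    np.fill_diagonal(denom, np.inf)
    denom = np.where(np.abs(denom) > _EPS, denom, _EPS)
    div += 4.0 * float(np.sum((s * shrunk)[:, None] / denom))
    return -m * n * tau2 + residual + tau2 * div


def _sure_svht_value(
    s: np.ndarray, shape: tuple[int, int], tau2: float, lam: float
) -> float:
    """Complex-data SURE of the hard-thresholding estimator at ``lam``."""
    m, n = shape
    p = min(m, n)
    s = s[:p]
    kept = s > lam
    residual = float(np.sum(s[~kept] ** 2))

    div = float(np.sum(kept)) * (2 + 2 * abs(m - n))
    s2 = s**2
    denom = s2[:, None] - s2[None, :]
    np.fill_diagonal(denom, np.inf)
    denom = np.where(np.abs(denom) > _EPS, denom, _EPS)
    div += 4.0 * float(np.sum((s2 * kept)[:, None] / denom))
    return -m * n * tau2 + residual + tau2 * div


def sure_svt(
    singular_values: np.ndarray,
    shape: tuple[int, int],
    noise_sd: float,
    lambda_grid: np.ndarray | None = None,
) -> ThresholdResult:
    """Threshold minimizing the unbiased MSE estimate of soft thresholding.

    The default grid is 200 logarithmically spaced points spanning
    ``[0.1 * noise_sd, sigma_1]`` (plus lambda = 0); the SVT risk is smooth
    in lambda so this density is ample.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    s = np.sort(np.asarray(singular_values, dtype=float))[::-1]
    if noise_sd == 0:
        return ThresholdResult(lam=0.0, rank=int(np.sum(s > 0)), risk_curve=[(0.0, 0.0)])
    if lambda_grid is None:
        top = s[0] if s.size and s[0] > 0 else noise_sd
        lambda_grid = np.concatenate(
            [[0.0], np.geomspace(0.1 * noise_sd, top, 200)]
        )
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size < 2:
        raise ValueError("lambda grid must contain at least 2 points")
    tau2 = 2.0 * noise_sd**2
    risks = [_sure_svt_value(s, shape, tau2, lam) for lam in lambda_grid]
    best = int(np.argmin(risks))
    lam = float(lambda_grid[best])
    return ThresholdResult(
        lam=lam,
        rank=int(np.sum(s > lam)),
        risk_curve=list(zip(lambda_grid.tolist(), map(float, risks))),
    )


def sure_svht(
    singular_values: np.ndarray, shape: tuple[int, int], noise_sd: float
) -> ThresholdResult:
    """Rank minimizing the unbiased MSE estimate of hard thresholding.

    The risk is piecewise constant in lambda, so only the midpoints between
    consecutive singular values (one candidate per retained rank) need to
    be evaluated.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    s = np.sort(np.asarray(singular_values, dtype=float))[::-1]
    p = s.size
    if noise_sd == 0:
        return ThresholdResult(lam=0.0, rank=int(np.sum(s > 0)))
    # Candidate lambda for retained rank r: midpoint between s_r and s_{r+1}.
    candidates = [(float(s[0] + 1.0), 0)]
    for r in range(1, p):
        candidates.append((float(0.5 * (s[r - 1] + s[r])), r))
    candidates.append((0.0, p))
    tau2 = 2.0 * noise_sd**2
    risks = [_sure_svht_value(s, shape, tau2, lam) for lam, _ in candidates]
    best = int(np.argmin(risks))
    lam, rank = candidates[best]
    return ThresholdResult(
        lam=lam,
        rank=rank,
        risk_curve=[(lam_, float(r_)) for (lam_, _), r_ in zip(candidates, risks)],
    )


def _mp_quantile(gamma: float, q: float) -> float:
    """``q``-quantile of the Marchenko-Pastur eigenvalue distribution.

    Eigenvalue distribution of ``(1/n) E E†`` for an m x n matrix of unit
    variance entries, ``gamma = m/n <= 1``; computed by numerical
    integration of the density.
    """
    a = (1.0 - np.sqrt(gamma)) ** 2
    b = (1.0 + np.sqrt(gamma)) ** 2
    x = np.linspace(a, b, 4001)
    with np.errstate(invalid="ignore"):
        density = np.sqrt(np.maximum((b - x) * (x - a), 0.0)) / (
            2.0 * np.pi * gamma * np.maximum(x, _EPS)
        )
    cdf = np.concatenate([[0.0], np.cumsum((density[1:] + density[:-1]) / 2 * np.diff(x))])
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, x))


def estimate_noise_sd(values: np.ndarray) -> float:
    """Estimate the per-channel noise SD from trailing singular values.

    The median of the trailing half of the singular-value spectrum is
    matched against the corresponding Marchenko-Pastur quantile of a
    pure-noise matrix of the same shape (the trailing half of a descending
    spectrum spans quantiles 0-0.5, so its median sits at the 0.25
    quantile). Signal components, assumed few, perturb only the leading
    singular values and leave the estimator nearly unbiased.
    """
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    m, n = values.shape
    p, q = min(m, n), max(m, n)
    if p < 8:
        raise ValueError("matrix too small for noise estimation (min dim >= 8)")
    s = scipy.linalg.svd(np.asarray(values, dtype=complex), compute_uv=False)
    trailing = s[p - p // 2 :]
    med = float(np.median(trailing))
    if med == 0.0:
        return 0.0
    x_q = _mp_quantile(p / q, 0.25)
    # singular value = noise_sd * sqrt(2 * n_big * x) for MP eigenvalue x
    return med / np.sqrt(2.0 * q * x_q)


def resolve_noise_sd(spec: ThresholdSpec, values: np.ndarray) -> float | None:
    """Noise SD to use for threshold selection, per the spec's policy."""
    if spec.mode == "fixed_rank":
        return None
    if spec.noise_sd == "estimate":
        return estimate_noise_sd(values)
    if spec.noise_sd is None:
        raise ValueError(
            f"threshold mode {spec.mode!r} requires a noise SD "
            "(give a value or 'estimate')"
        )
    return float(spec.noise_sd)
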