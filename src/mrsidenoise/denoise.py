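"""Denoising pipelines for MRSI data.

Four pipelines, all built from rank truncation / shrinkage of a matrix
lifting of the data:

* ``denoise_lp`` — linear-predictability (Hankel) denoising, voxel-wise;
  no data is shared across voxels.
* ``denoise_st_global`` — spatiotemporal denoising of the Casorati matrix
  of all masked voxels at once.
* ``denoise_st_local`` — spatiotemporal denoising within overlapping 3-D
  patches; overlapping estimates are averaged with uniform weights.
* ``denoise_lora`` — spatiotemporal denoising (global or patch-wise)
  followed by voxel-wise linear-predictability denoising.

Every pipeline returns a :class:`DenoiseOutput` that retains the truncated
SVD factors actually used, which is what makes closed-form post-denoising
uncertainty propagation possible downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    HankelLayout,
    LowRankFactors,
    build_casorati,
    build_hankel,
    scatter_casorati,
    svht_by_lambda,
    svht_by_rank,
    svt,
    unhankel_edge,
)
from .data import MRSIData
from .rank_select import (
    ThresholdResult,
    ThresholdSpec,
    mp_threshold,
    resolve_noise_sd,
    sure_svht,
    sure_svt,
)

__all__ = [
    "PatchSpec",
    "FactorEntry",
    "DenoiseOutput",
    "denoise_lp",
    "denoise_st_global",
    "denoise_st_local",
    "denoise_lora",
    "threshold_matrix",
]


@dataclass(frozen=True)
class PatchSpec:
    """3-D patch size and stride for local (patch-wise) denoising.

    Patches are anchored at stride-lattice origins and enumerated fully
    inside the grid (origins ``0, stride, 2*stride, ...`` up to
    ``grid - size``; the final origin is clamped to ``grid - size`` so the
    far edge is always covered). A patch larger than the grid is clipped
    to the grid with a warning.
    """

    size: tuple[int, int, int] = (3, 3, 1)
    stride: int = 1

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.size):
            raise ValueError("patch size components must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def origins(self, grid_shape: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        axes = []
        for g, p in zip(grid_shape, self.size):
            if p > g:
                warnings.warn(
                    f"patch size {p} exceeds grid extent {g}; clipping to grid",
                    stacklevel=3,
                )
                axes.append([0])
                continue
            pts = list(range(0, g - p + 1, self.stride))
            if pts[-1] != g - p:
                pts.append(g - p)
            axes.append(pts)
        return [
            (x, y, z) for x in axes[0] for y in axes[1] for z in axes[2]
        ]

    def patch_slices(
        self, origin: tuple[int, int, int], grid_shape: tuple[int, int, int]
    ) -> tuple[slice, slice, slice]:
        return tuple(
            slice(o, min(o + p, g))
            for o, p, g in zip(origin, self.size, grid_shape)
        )


@dataclass
class FactorEntry:
    """SVD factors of one thresholded matrix, with provenance.

    ``voxel_index`` maps Casorati columns to grid coordinates (ST methods)
    or holds the single voxel coordinate (LP). ``stage`` distinguishes the
    two passes of LORA.
    """

    factors: LowRankFactors
    voxel_index: list[tuple[int, int, int]]
    patch_origin: tuple[int, int, int] | None = None
    stage: str = "st"  # "st" | "lp"
    threshold: ThresholdResult | None = None


@dataclass
class DenoiseOutput:
    """Denoised data plus the factorizations that produced it."""

    data: MRSIData
    method: str
    factors: list[FactorEntry] = field(default_factory=list)
    overlap_count: np.ndarray | None = None
    noise_sd: float | None = None  # per-channel SD used/known for the input

    def st_factor_entries(self) -> list[FactorEntry]:
        return [f for f in self.factors if f.stage == "st"]


def threshold_matrix(
    matrix: np.ndarray, spec: ThresholdSpec, noise_sd: float | None
) -> tuple[np.ndarray, LowRankFactors, ThresholdResult]:
    """Apply a threshold policy to one matrix; returns the denoised matrix,
    the retained factors, and the selected threshold."""
    import scipy.linalg

    if spec.mode == "fixed_rank":
        rank = min(spec.fixed_rank, *matrix.shape)
        denoised, factors = svht_by_rank(matrix, rank)
        return denoised, factors, ThresholdResult(lam=0.0, rank=rank)

    if noise_sd is None:
        noise_sd = resolve_noise_sd(spec, matrix)
    s = scipy.linalg.svd(np.asarray(matrix, dtype=complex), compute_uv=False)
    if spec.mode == "mp":
        res = mp_threshold(s, matrix.shape, noise_sd)
        denoised, factors = svht_by_lambda(matrix, res.lam)
    elif spec.mode == "sure_svht":
        res = sure_svht(s, matrix.shape, noise_sd)
        denoised, factors = svht_by_rank(matrix, res.rank)
    else:  # sure_svt
        res = sure_svt(s, matrix.shape, noise_sd)
        denoised, factors = svt(matrix, res.lam)
    return denoised, factors, res


def _study_noise_sd(data: MRSIData, spec: ThresholdSpec) -> float | None:
    """Per-channel noise SD for threshold selection: explicit spec value,
    else the value recorded on the data, else None (estimated per matrix)."""
    if spec.mode == "fixed_rank":
        return None
    if isinstance(spec.noise_sd, (int, float)):
        return float(spec.noise_sd)
    if spec.noise_sd == "estimate":
        if data.noise_sd is not None and data.noise_sd > 0:
            return float(data.noise_sd)
        return None  # estimate from each matrix as it is built
    raise ValueError("threshold spec carries no usable noise SD")


def denoise_lp(
    data: MRSIData,
    rank: int,
    layout: HankelLayout | None = None,
) -> DenoiseOutput:
    """Voxel-wise linear-predictability (Hankel) denoising at fixed rank.

    Each masked voxel's FID is lifted to a near-square Hankel matrix,
    hard-truncated to ``rank``, and read back from the first row and last
    column of the truncated matrix (no re-Hankelization). Unmasked voxels
    pass through unchanged.
    """
    layout = layout or HankelLayout.default(data.n_t)
    if rank > min(layout.n_rows, layout.n_cols):
        raise ValueError(
            f"rank {rank} exceeds Hankel dimensions "
            f"{(layout.n_rows, layout.n_cols)}"
        )
    out_fid = data.fid.copy()
    entries: list[FactorEntry] = []
    for xyz in np.argwhere(data.mask):
        x, y, z = (int(c) for c in xyz)
        h = build_hankel(data.fid[x, y, z, :], layout)
        h_bar, factors = svht_by_rank(h, rank, backend="auto")
        out_fid[x, y, z, :] = unhankel_edge(h_bar, layout)
        entries.append(
            FactorEntry(factors=factors, voxel_index=[(x, y, z)], stage="lp")
        )
    return DenoiseOutput(
        data=data.copy(fid=out_fid),
        method="lp",
        factors=entries,
        noise_sd=data.noise_sd,
    )


def denoise_st_global(data: MRSIData, threshold: ThresholdSpec) -> DenoiseOutput:
    """Spatiotemporal denoising of the full-grid Casorati matrix."""
    if data.n_masked < 2:
        raise ValueError("global ST denoising needs at least 2 masked voxels")
    matrix, voxel_index = build_casorati(data.fid, data.mask)
    noise_sd = _study_noise_sd(data, threshold)
    denoised, factors, res = threshold_matrix(matrix, threshold, noise_sd)
    out_fid = data.fid.copy()
    scatter_casorati(denoised, voxel_index, out_fid)
    return DenoiseOutput(
        data=data.copy(fid=out_fid),
        method="st_global",
        factors=[
            FactorEntry(factors=factors, voxel_index=voxel_index, threshold=res)
        ],
        noise_sd=noise_sd if noise_sd is not None else data.noise_sd,
    )


def denoise_st_local(
    data: MRSIData, threshold: ThresholdSpec, patch: PatchSpec
) -> DenoiseOutput:
    """Patch-wise spatiotemporal denoising with uniform overlap averaging.

    ST denoising is applied within each patch (restricted to masked
    voxels); a voxel covered by several overlapping patches receives the
    arithmetic mean of the patch estimates. The noise is assumed
    stationary, so a single grid-level noise SD is used for threshold
    selection in every patch.
    """
    noise_sd = _study_noise_sd(data, threshold)
    if threshold.mode != "fixed_rank" and noise_sd is None:
        # estimate once, globally, for stationary noise
        matrix, _ = build_casorati(data.fid, data.mask)
        from .rank_select import estimate_noise_sd

        noise_sd = estimate_noise_sd(matrix)

    accum = np.zeros_like(data.fid)
    count = np.zeros(data.grid_shape, dtype=int)
    entries: list[FactorEntry] = []
    for origin in patch.origins(data.grid_shape):
        slices = patch.patch_slices(origin, data.grid_shape)
        sub_mask = np.zeros(data.grid_shape, dtype=bool)
        sub_mask[slices] = data.mask[slices]
        if sub_mask.sum() < 2:
            continue  # ST needs at least 2 Casorati columns
        matrix, voxel_index = build_casorati(data.fid, sub_mask)
        denoised, factors, res = threshold_matrix(matrix, threshold, noise_sd)
        for j, (x, y, z) in enumerate(voxel_index):
            accum[x, y, z, :] += denoised[:, j]
            count[x, y, z] += 1
        entries.append(
            FactorEntry(
                factors=factors,
                voxel_index=voxel_index,
                patch_origin=tuple(origin),
                threshold=res,
            )
        )
    if not entries:
        raise ValueError("no patch contained >= 2 masked voxels")
    covered = count > 0
    out_fid = data.fid.copy()
    out_fid[covered] = accum[covered] / count[covered][:, None]
    return DenoiseOutput(
        data=data.copy(fid=out_fid),
        method="st_local",
        factors=entries,
        overlap_count=count,
        noise_sd=noise_sd if noise_sd is not None else data.noise_sd,
    )


def denoise_lora(
    data: MRSIData,
    st_threshold: ThresholdSpec,
    lp_rank: int = 20,
    patch: PatchSpec | None = None,
    layout: HankelLayout | None = None,
) -> DenoiseOutput:
    """Sequential spatiotemporal-then-linear-predictability denoising.

    The ST stage is global when ``patch`` is None, patch-wise otherwise;
    the LP stage always runs voxel-wise at the fixed ``lp_rank`` (default
    20, a heuristic generous enough for typical numbers of spectral
    peaks).
    """
    if patch is None:
        st_out = denoise_st_global(data, st_threshold)
        method = "lora_global"
    else:
        st_out = denoise_st_local(data, st_threshold, patch)
        method = "lora_local"
    lp_out = denoise_lp(st_out.data, lp_rank, layout)
    return DenoiseOutput(
        data=lp_out.data,
        method=method,
        factors=st_out.factors + lp_out.factors,
        overlap_count=st_out.overlap_count,
        noise_sd=st_out.noise_sd,
    )
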