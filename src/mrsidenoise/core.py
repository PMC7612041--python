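"""Matrix-level low-rank primitives.

Truncated SVD, hard and soft singular-value thresholding, and the two
matrix liftings used in spectroscopic denoising: the Hankel matrix of a
single FID (linear predictability) and the Casorati matrix of an MRSI
grid (spatiotemporal separability).

All SVDs use the full (LAPACK) decomposition rather than a randomized
backend so that results are bit-reproducible for a given input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "LowRankFactors",
    "HankelLayout",
    "truncated_svd",
    "svht_by_rank",
    "svht_by_lambda",
    "svt",
    "build_hankel",
    "unhankel_edge",
    "build_casorati",
    "scatter_casorati",
]

#: Singular values below RANK_TOL * sigma_1 are treated as numerically zero.
RANK_TOL = 1e-12


@dataclass
class LowRankFactors:
    """Truncated SVD factors ``U_hat @ diag(S_hat) @ V_hat.conj().T``.

    For soft thresholding ``S_hat`` stores the *shrunk* singular values
    ``(sigma_i - lambda)_+`` of the retained components.
    """

    U_hat: np.ndarray  # (M, r)
    S_hat: np.ndarray  # (r,) real, descending
    V_hat: np.ndarray  # (N, r)
    rank: int
    shrinkage: str = "hard"  # "hard" | "soft"
    threshold_lambda: float | None = None

    def reconstruct(self) -> np.ndarray:
        """Return ``U_hat @ diag(S_hat) @ V_hat†``."""
        if self.rank == 0:
            return np.zeros((self.U_hat.shape[0], self.V_hat.shape[0]), dtype=complex)
        return (self.U_hat * self.S_hat) @ self.V_hat.conj().T

    @property
    def shape(self) -> tuple[int, int]:
        return (self.U_hat.shape[0], self.V_hat.shape[0])


@dataclass(frozen=True)
class HankelLayout:
    """Shape of the Hankel lifting of a length-``n_time`` signal.

    The matrix has shape ``(n_time - n_cols + 1, n_cols)`` with entry
    ``(i, j) = s[i + j]`` (0-based).
    """

    n_time: int
    n_cols: int

    def __post_init__(self) -> None:
        if not 1 <= self.n_cols <= self.n_time:
            raise ValueError(
                f"n_cols must be in [1, {self.n_time}], got {self.n_cols}"
            )

    @property
    def n_rows(self) -> int:
        return self.n_time - self.n_cols + 1

    @staticmethod
    def default(n_time: int) -> "HankelLayout":
        # Near-square lifting maximizes the available rank budget.
        return HankelLayout(n_time, n_time // 2 + 1)


def _full_svd(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = np.ascontiguousarray(np.asarray(values, dtype=complex))
    u, s, vh = scipy.linalg.svd(m, full_matrices=False, lapack_driver="gesdd")
    return u, s, vh


def truncated_svd(values: np.ndarray, rank: int) -> LowRankFactors:
    """Best rank-``rank`` factors of a matrix (Eckart-Young truncation)."""
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    mmin = min(values.shape)
    if not 0 <= rank <= mmin:
        raise ValueError(f"rank must be in [0, {mmin}], got {rank}")
    u, s, vh = _full_svd(values)
    return LowRankFactors(
        U_hat=u[:, :rank].copy(),
        S_hat=s[:rank].copy(),
        V_hat=vh[:rank].conj().T.copy(),
        rank=rank,
        shrinkage="hard",
    )


def _lanczos_svd(values: np.ndarray, rank: int) -> LowRankFactors:
    """Top-``rank`` triples via Lanczos iteration with a fixed start vector.

    Deterministic (the start vector is fixed, not random) and much faster
    than a full decomposition when ``rank`` is tiny relative to the matrix.
    """
    from scipy.sparse.linalg import svds

    m = np.asarray(values, dtype=complex)
    v0 = np.full(min(m.shape), 1.0)
    u, s, vh = svds(m, k=rank, v0=v0, which="LM")
    order = np.argsort(s)[::-1]
    return LowRankFactors(
        U_hat=np.ascontiguousarray(u[:, order]),
        S_hat=s[order].copy(),
        V_hat=np.ascontiguousarray(vh[order, :].conj().T),
        rank=rank,
        shrinkage="hard",
    )


def svht_by_rank(
    values: np.ndarray, rank: int, backend: str = "full"
) -> tuple[np.ndarray, LowRankFactors]:
    """Hard singular-value truncation retaining the top ``rank`` triples.

    ``backend='full'`` (default) uses the full LAPACK SVD; ``'auto'``
    switches to a deterministic Lanczos solver when only a handful of
    triples are needed from a large matrix.
    """
    values = np.asarray(values)
    if (
        backend == "auto"
        and values.ndim == 2
        and 1 <= rank <= 4
        and min(values.shape) >= 64
    ):
        factors = _lanczos_svd(values, rank)
    else:
        factors = truncated_svd(values, rank)
    return factors.reconstruct(), factors


def svht_by_lambda(
    values: np.ndarray, lam: float
) -> tuple[np.ndarray, LowRankFactors]:
    """Hard thresholding: retain singular values strictly above ``lam``.

    A singular value exactly at the threshold is discarded (Heaviside
    convention H(0) = 0), which makes noise-edge thresholds conservative.
    """
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    values = np.asarray(values)
    u, s, vh = _full_svd(values)
    rank = int(np.sum(s > lam))
    factors = LowRankFactors(
        U_hat=u[:, :rank].copy(),
        S_hat=s[:rank].copy(),
        V_hat=vh[:rank].conj().T.copy(),
        rank=rank,
        shrinkage="hard",
        threshold_lambda=float(lam),
    )
    return factors.reconstruct(), factors


def svt(values: np.ndarray, lam: float) -> tuple[np.ndarray, LowRankFactors]:
    """Soft thresholding: shrink singular values to ``(sigma_i - lam)_+``."""
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    values = np.asarray(values)
    u, s, vh = _full_svd(values)
    shrunk = s - lam
    rank = int(np.sum(shrunk > 0))
    factors = LowRankFactors(
        U_hat=u[:, :rank].copy(),
        S_hat=shrunk[:rank].copy(),
        V_hat=vh[:rank].conj().T.copy(),
        rank=rank,
        shrinkage="soft",
        threshold_lambda=float(lam),
    )
    return factors.reconstruct(), factors


def build_hankel(signal: np.ndarray, layout: HankelLayout | None = None) -> np.ndarray:
    """Hankel matrix of a 1-D signal: entry ``(i, j) = s[i + j]``."""
    signal = np.asarray(signal).ravel()
    m = signal.shape[0]
    if layout is None:
        layout = HankelLayout.default(m)
    if layout.n_time != m:
        raise ValueError(
            f"layout expects signal of length {layout.n_time}, got {m}"
        )
    k = layout.n_cols
    return scipy.linalg.hankel(signal[: m - k + 1], signal[m - k :])


def unhankel_edge(h: np.ndarray, layout: HankelLayout) -> np.ndarray:
    """Recover a signal from the first row and last column of ``h``.

    This is the "soft" inverse lifting: for a matrix that is no longer
    exactly Hankel (e.g. after rank truncation) only the edge entries are
    used; no anti-diagonal averaging or re-Hankelization is performed.
    """
    h = np.asarray(h)
    if h.shape != (layout.n_rows, layout.n_cols):
        raise ValueError(
            f"expected shape {(layout.n_rows, layout.n_cols)}, got {h.shape}"
        )
    return np.concatenate([h[0, :], h[1:, -1]])


def build_casorati(
    fid: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Casorati matrix (n_t x n_vox) of a 4-D (x, y, z, t) grid.

    Column ``j`` is the full time series of the ``j``-th masked voxel in
    row-major (x, y, z) order; ``voxel_index`` maps columns back to grid
    coordinates so the matrix layout is grid-layout independent.
    """
    fid = np.asarray(fid)
    if fid.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, t) array")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fid.shape[:3]:
        raise ValueError("mask shape must match the spatial grid")
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError("mask selects no voxels")
    voxel_index = [tuple(int(c) for c in xyz) for xyz in coords]
    matrix = fid[mask].T  # (n_t, n_vox)
    return np.ascontiguousarray(matrix), voxel_index


def scatter_casorati(
    matrix: np.ndarray,
    voxel_index: list[tuple[int, int, int]],
    out: np.ndarray,
) -> np.ndarray:
    """Scatter Casorati columns back into a 4-D grid (in place on ``out``)."""
    for j, (x, y, z) in enumerate(voxel_index):
        out[x, y, z, :] = matrix[:, j]
    return out
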