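"""In-memory container for 4-D MRSI time-domain data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MRSIData"]


@dataclass
class MRSIData:
    """Complex time-domain MRSI grid.

    Parameters
    ----------
    fid
        Complex 4-D array, shape ``(n_x, n_y, n_z, n_t)``; the last axis is
        the free induction decay of each voxel.
    dwell_time
        Sampling interval of the FID in seconds.
    mask
        Boolean 3-D array selecting the voxels that carry data. Defaults to
        all voxels.
    noise_sd
        Standard deviation of the i.i.d. Gaussian noise in each of the real
        and imaginary channels (per time point, per voxel), if known.
    """

    fid: np.ndarray
    dwell_time: float
    mask: np.ndarray | None = None
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        self.fid = np.asarray(self.fid, dtype=complex)
        if self.fid.ndim != 4:
            raise ValueError("fid must be 4-D (x, y, z, t)")
        if self.fid.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.mask is None:
            self.mask = np.ones(self.fid.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.fid.shape[:3]:
                raise ValueError("mask shape must match spatial grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.fid.shape[:3]

    @property
    def n_t(self) -> int:
        return self.fid.shape[3]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def time_axis(self) -> np.ndarray:
        """Sample times ``n * dwell_time`` in seconds."""
        return np.arange(self.n_t) * self.dwell_time

    @property
    def spectral_bandwidth(self) -> float:
        return 1.0 / self.dwell_time

    def copy(self, fid: np.ndarray | None = None) -> "MRSIData":
        return MRSIData(
            fid=self.fid.copy() if fid is None else np.asarray(fid, dtype=complex),
            dwell_time=self.dwell_time,
            mask=self.mask.copy(),
            noise_sd=self.noise_sd,
        )
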