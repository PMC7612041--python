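"""Reading and writing MRSI data.

The primary on-disk format is a NIfTI-MRS-style complex 4-D NIfTI-2 file:
time along the 4th dimension, the dwell time in seconds in ``pixdim[4]``,
and a JSON header extension (ecode 44, as NIfTI-MRS uses) carrying the
noise level and provenance. Masks travel as 3-D integer NIfTI sidecars.
A ``.npz`` array container is supported as a fallback for toolchains
without NIfTI support.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .data import MRSIData

__all__ = ["read_mrsi", "write_mrsi", "write_mask", "read_mask"]

_JSON_ECODE = 44  # NIfTI-MRS JSON header extension code


def write_mrsi(
    data: MRSIData,
    path: str | Path,
    provenance: dict | None = None,
    overwrite: bool = False,
) -> None:
    """Write 4-D complex MRSI data (NIfTI-2 or ``.npz`` by extension)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    meta = {"noise_sd": data.noise_sd}
    if provenance:
        meta["provenance"] = provenance
    if path.suffix == ".npz":
        np.savez(
            path,
            fid=data.fid,
            dwell_time=data.dwell_time,
            mask=data.mask,
            meta=json.dumps(meta),
        )
        return
    img = nib.Nifti2Image(np.asarray(data.fid, dtype=np.complex128), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, data.dwell_time))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    ext = nib.nifti1.Nifti1Extension(_JSON_ECODE, json.dumps(meta).encode("utf-8"))
    img.header.extensions.append(ext)
    nib.save(img, path)
    if not np.all(data.mask):
        write_mask(data.mask, _mask_path(path), overwrite=overwrite)


def _mask_path(path: Path) -> Path:
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            return path.with_name(stem[: -len(suf)] + "_mask" + suf)
    return path.with_name(stem + "_mask.nii")


def write_mask(mask: np.ndarray, path: str | Path, overwrite: bool = False) -> None:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    img = nib.Nifti2Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4))
    nib.save(img, path)


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asanyarray(nib.load(str(path)).dataobj)
    if arr.ndim != 3:
        raise ValueError(f"mask must be 3-D, got {arr.ndim}-D")
    return arr.astype(bool)


def read_mrsi(path: str | Path, mask_path: str | Path | None = None) -> MRSIData:
    """Read 4-D complex MRSI data written by :func:`write_mrsi`.

    A mask sidecar is honoured if ``mask_path`` is given or the default
    sidecar file exists next to the data.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            return MRSIData(
                fid=f["fid"],
                dwell_time=float(f["dwell_time"]),
                mask=f["mask"],
                noise_sd=meta.get("noise_sd"),
            )
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise ValueError(
            f"expected 4-D (x, y, z, t) data, got {arr.ndim}-D in {path}"
        )
    if not np.iscomplexobj(arr):
        raise ValueError(
            f"{path} holds real-valued data; complex time-domain data required"
        )
    dwell = float(img.header.get_zooms()[3])
    if dwell <= 0:
        raise ValueError(
            f"{path}: missing dwell time (pixdim[4] must be the dwell time "
            "in seconds)"
        )
    noise_sd = None
    for ext in img.header.extensions:
        if ext.get_code() == _JSON_ECODE:
            try:
                meta = json.loads(ext.get_content().decode("utf-8"))
            except (UnicodeDecodeError, json.JSONDecodeError):
                continue
            noise_sd = meta.get("noise_sd")
    if mask_path is None:
        candidate = _mask_path(path)
        mask_path = candidate if candidate.exists() else None
    mask = read_mask(mask_path) if mask_path is not None else None
    return MRSIData(fid=arr, dwell_time=dwell, mask=mask, noise_sd=noise_sd)
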