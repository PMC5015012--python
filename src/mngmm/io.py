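"""Reading and writing intensity volumes and label maps.

NIfTI-1 (.nii/.nii.gz) and Analyze 7.5 (.hdr/.img) go through nibabel;
single-channel PNG/TIFF slices go through imageio.  Arrays are kept in the
on-disk index order of the file; no reorientation is performed.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .types import LabelMap, SegmentationResult, Volume

_NIB_EXTS = (".nii", ".nii.gz", ".hdr", ".img", ".img.gz")
_IMG_EXTS = (".png", ".tif", ".tiff")


def _ext(path: str) -> str:
    lower = str(path).lower()
    for e in (".nii.gz", ".img.gz"):
        if lower.endswith(e):
            return e
    return os.path.splitext(lower)[1]


def _load_array(path: str) -> np.ndarray:
    ext = _ext(path)
    if ext in _NIB_EXTS:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        return np.squeeze(arr)
    if ext in _IMG_EXTS:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            # Accept gray images saved with redundant channels.
            if arr.shape[-1] in (3, 4) and np.all(arr[..., :3] == arr[..., :1]):
                arr = arr[..., 0]
            else:
                raise ValueError(f"{path}: expected a single-channel image")
        return arr
    raise ValueError(f"{path}: unsupported format {ext!r} (NIfTI, Analyze, PNG, TIFF)")


def _spacing_from_header(path: str, ndim: int):
    if _ext(path) in _NIB_EXTS:
        try:
            zooms = nib.load(str(path)).header.get_zooms()
            return tuple(float(z) for z in zooms[:ndim])
        except Exception:
            return None
    return None


def read_volume(path: str, mask_path: Optional[str] = None) -> Volume:
    """Read an intensity image and return it as a :class:`Volume`.

    Without an explicit mask, brain tissue defaults to ``data > 0``
    (skull-stripped images store zero outside the brain).
    """
    if not os.path.exists(path) and not os.path.exists(str(path)):
        raise FileNotFoundError(path)
    try:
        data = _load_array(path).astype(float)
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # nibabel/imageio-specific parse failures
        raise ValueError(f"could not read image {path!r}: {exc}") from exc
    mask = None
    if mask_path is not None:
        mask = _load_array(mask_path) > 0
        if mask.shape != data.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape {data.shape}"
            )
    return Volume(data=data, spacing=_spacing_from_header(path, data.ndim), mask=mask)


def _save_array(arr: np.ndarray, path: str, spacing=None) -> None:
    ext = _ext(path)
    if ext in _NIB_EXTS:
        affine = np.eye(4)
        if spacing is not None:
            for i, s in enumerate(spacing[:3]):
                affine[i, i] = s
        cls = nib.Nifti1Image if ext in (".nii", ".nii.gz") else nib.AnalyzeImage
        img = cls(arr, affine)
        nib.save(img, str(path))
    elif ext in _IMG_EXTS:
        if arr.ndim != 2:
            raise ValueError("PNG/TIFF output requires a 2D array")
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"{path}: unsupported output format {ext!r}")


def write_volume(volume: Volume, path: str) -> None:
    """Write intensities as float32 (NIfTI/Analyze) or uint16 (PNG)."""
    arr = volume.data.astype(np.float32)
    if _ext(path) in _IMG_EXTS:
        arr = np.clip(np.rint(volume.data), 0, 65535).astype(np.uint16)
    _save_array(arr, path, volume.spacing)


def write_labels(result: Union[SegmentationResult, LabelMap], path: str) -> None:
    """Write tissue labels as an unsigned 8-bit image; codes survive round-trip."""
    labels = result.labels if isinstance(result, SegmentationResult) else result
    if not isinstance(labels, LabelMap):
        labels = LabelMap(np.asarray(labels))  # validates codes
    _save_array(labels.labels.astype(np.uint8), path)


def read_labels(path: str) -> LabelMap:
    """Read a label image back into a :class:`LabelMap`."""
    return LabelMap(_load_array(path).astype(np.int64))
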