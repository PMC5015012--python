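"""Core data containers for intensity volumes, label maps, and segmentations.

The segmentation pipeline works on skull-stripped scalar images (2D slices or
3D volumes).  Background voxels carry intensity 0; the brain is described by a
boolean mask.  Tissue labels use a fixed integer code ordered by typical
T1-weighted intensity:

    0 = background, 1 = CSF, 2 = gray matter, 3 = white matter
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .gmm import MixtureModel

#: Tissue label codes, ascending by expected T1 intensity.
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
TISSUE_NAMES = {BACKGROUND: "background", CSF: "CSF", GM: "GM", WM: "WM"}


@dataclass
class Volume:
    """A scalar intensity image (2D or 3D) with an optional brain mask.

    Parameters
    ----------
    data:
        Intensity array, 2 or 3 dimensions, any float/integer dtype.
    spacing:
        Physical voxel size per axis in mm.  Defaults to isotropic 1.0.
    mask:
        Boolean array marking brain tissue.  When omitted, all voxels with
        intensity strictly greater than zero are treated as brain — the
        convention for skull-stripped images with zeroed background.
    """

    data: np.ndarray
    spacing: Optional[Tuple[float, ...]] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D image, got ndim={self.data.ndim}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
            if len(self.spacing) != self.data.ndim:
                raise ValueError("spacing length must match image dimensionality")
        if self.mask is None:
            self.mask = self.data > 0
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match data shape {self.data.shape}"
                )
        if self.mask.any() and not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("intensities inside the brain mask must be finite")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def n_brain(self) -> int:
        """Number of voxels inside the brain mask."""
        return int(self.mask.sum())

    @property
    def brain_values(self) -> np.ndarray:
        """1D array of intensities at masked voxels (C order)."""
        return self.data[self.mask]

    def require_brain(self) -> None:
        """Raise if the volume has no brain tissue to operate on."""
        if self.n_brain < 1:
            raise ValueError("volume has an empty brain mask; nothing to segment")


@dataclass
class LabelMap:
    """Integer tissue labels sharing the geometry of a :class:`Volume`."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise ValueError("labels must be integers")
            self.labels = rounded.astype(np.int64)
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, CSF, GM, WM])
        if bad.size:
            raise ValueError(f"labels contain invalid codes {bad.tolist()}; allowed: 0..3")

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.labels.shape

    def class_counts(self) -> dict:
        """Voxel count per label code present in the map."""
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def check_mask(self, mask: np.ndarray) -> None:
        """Verify labels are 0 exactly where ``mask`` is false."""
        if self.labels.shape != mask.shape:
            raise ValueError("label/mask shape mismatch")
        if np.any(self.labels[~mask] != 0):
            raise ValueError("non-background labels found outside the mask")


@dataclass
class SegmentationResult:
    """Final output of the pipeline: posterior maps plus a hard labeling.

    ``posteriors`` has shape (K, *image_shape); entries at masked voxels lie
    in [0, 1] and are normalized over classes for export.  ``labels`` assigns
    each masked voxel ``1 + argmax_k posterior`` (ties to the lower class).
    ``models`` maps patch id -> fitted mixture model; ``patch_map`` records
    each voxel's home patch (0 outside the brain).
    """

    posteriors: np.ndarray
    labels: LabelMap
    models: dict = field(default_factory=dict)
    patch_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if self.posteriors.shape[1:] != self.labels.shape:
            raise ValueError("posterior maps must share the label map geometry")

    @property
    def n_classes(self) -> int:
        return self.posteriors.shape[0]
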