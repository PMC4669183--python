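"""Volumetric containers with physical grid metadata.

All spatial quantities are in millimetres.  A volume is an axis-aligned
regular grid; voxel ``(i, j, k)`` has its centre at
``origin + spacing * (i, j, k)``.  Tissue classes are encoded as integers:
air = 0, soft tissue = 1, bone = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

AIR = 0
SOFT = 1
BONE = 2
TISSUE_CLASSES = (AIR, SOFT, BONE)
TISSUE_NAMES = {AIR: "air", SOFT: "soft", BONE: "bone"}


class GridMismatchError(ValueError):
    """Two volumes do not share shape/spacing/origin."""


@dataclass
class ImageVolume:
    """A 3-D scalar field on a regular anisotropic grid.

    Parameters
    ----------
    data
        3-D array of voxel values.
    spacing
        Voxel size in mm along each axis.
    origin
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    # -- grid helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on this grid carrying ``data``."""
        return ImageVolume(np.asarray(data), self.spacing, self.origin)

    def same_grid(self, other: "ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def check_same_grid(self, other: "ImageVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    # -- I/O -----------------------------------------------------------

    def save(self, path: str, description: str = "") -> None:
        img = nib.Nifti1Image(np.asarray(self.data), self.affine)
        img.header.set_zooms(self.spacing)
        if description:
            img.header["descrip"] = description.encode()[:79]
        nib.save(img, path)

    @classmethod
    def load(cls, path: str) -> "ImageVolume":
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(np.asarray(img.affine)[:3, 3])
        return cls(data, tuple(float(z) for z in zooms), origin)


@dataclass
class LabelVolume(ImageVolume):
    """Integer tissue-class map over {air=0, soft=1, bone=2}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label volume must hold integers")
            self.data = rounded.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.data), TISSUE_CLASSES)
        if bad.size:
            raise ValueError(f"labels outside {{air, soft, bone}}: {bad.tolist()}")

    def like_labels(self, data: np.ndarray) -> "LabelVolume":
        return LabelVolume(np.asarray(data), self.spacing, self.origin)

    def class_mask(self, tissue: int) -> np.ndarray:
        return self.data == tissue

    def class_counts(self) -> dict[int, int]:
        return {t: int(np.count_nonzero(self.data == t)) for t in TISSUE_CLASSES}

    def save(self, path: str, description: str = "labels: air=0 soft=1 bone=2") -> None:
        super().save(path, description=description)

    @classmethod
    def load(cls, path: str) -> "LabelVolume":
        vol = ImageVolume.load(path)
        return cls(np.rint(np.asanyarray(vol.data)).astype(np.int16), vol.spacing, vol.origin)
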