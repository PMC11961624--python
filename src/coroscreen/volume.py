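"""Spatially referenced 3D volumes.

Every image in the pipeline lives on a regular grid in a canonical patient
frame with +x = patient right, +y = anterior, +z = superior.  Array axes are
ordered (x, y, z) so that index ``i`` along axis ``k`` sits at world
coordinate ``origin[k] + i * spacing[k]`` (mm).  NIfTI volumes are reoriented
to this frame on load via :func:`nibabel.as_closest_canonical` — nibabel's
canonical orientation is RAS, which matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "LabelMap",
    "Label",
    "load_volume",
    "save_volume",
    "load_labelmap",
]


class Label:
    """Integer codes used in phantom / segmentation label maps."""

    BACKGROUND = 0
    AORTA = 1
    LV_MYOCARDIUM = 2
    LV_CAVITY = 3
    PULMONARY_ARTERY = 4
    CORONARY_RCA = 5
    CORONARY_LCA = 6

    NAMES = {
        AORTA: "aorta",
        LV_MYOCARDIUM: "lv_myocardium",
        LV_CAVITY: "lv_cavity",
        PULMONARY_ARTERY: "pulmonary_artery",
        CORONARY_RCA: "coronary_rca",
        CORONARY_LCA: "coronary_lca",
    }


@dataclass
class ImageVolume:
    """A scalar 3D image with voxel spacing and world origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def world_coords(self, index) -> np.ndarray:
        """World coordinate (mm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def index_of(self, point_mm) -> np.ndarray:
        """Fractional voxel index of a world point."""
        return (np.asarray(point_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def physical_extent(self) -> np.ndarray:
        """Physical size of the grid (mm) counted as n_voxels * spacing."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def copy(self) -> "ImageVolume":
        return replace(self, data=self.data.copy())


@dataclass
class LabelMap(ImageVolume):
    """Integer-labelled volume on the same grid conventions as ImageVolume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.rint(self.data).astype(np.int16)

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def labels_present(self) -> list[int]:
        vals = np.unique(self.data)
        return [int(v) for v in vals if v != Label.BACKGROUND]


def _from_nifti(img: nib.Nifti1Image, as_labels: bool) -> ImageVolume:
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, k])) for k in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    cls = LabelMap if as_labels else ImageVolume
    return cls(data=data, spacing=spacing, origin=origin)


def load_volume(path) -> ImageVolume:
    """Load a NIfTI image and reorient it to the canonical RAS-like frame."""
    return _from_nifti(nib.load(str(path)), as_labels=False)


def load_labelmap(path) -> LabelMap:
    return _from_nifti(nib.load(str(path)), as_labels=True)


def save_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI with its diagonal RAS affine."""
    data = vol.data
    if isinstance(vol, LabelMap):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(np.asarray(data), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
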