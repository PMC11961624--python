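"""Aortic-root localization and fixed-size ROI cropping.

The proximal course of an anomalous coronary lives around the aortic root,
so classification operates on a fixed physical box around the point where
the aorta meets the left ventricle.  The reference point is the centroid of
the aorta/LV contact set, shifted 10 mm toward patient right and 10 mm
superior so more of the ascending aorta enters the field, and an
80 x 80 x 60 mm box around the shifted point is cropped.

"Right" is taken as patient +x in the canonical frame; the offset vector is
configurable because screen-right conventions differ between viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .volume import ImageVolume, Label, LabelMap

__all__ = [
    "RootPoint",
    "CropBox",
    "DEFAULT_EXTENT_MM",
    "DEFAULT_OFFSET_MM",
    "find_root_point",
    "compute_crop_box",
    "crop_volume",
    "naive_segment",
    "crop_case",
]

DEFAULT_EXTENT_MM = (80.0, 80.0, 60.0)
DEFAULT_OFFSET_MM = (10.0, 0.0, 10.0)
DEFAULT_PAD_HU = -1024.0


@dataclass(frozen=True)
class RootPoint:
    """Aorta/LV contact centroid and its offset-adjusted version (mm)."""

    point_mm: tuple[float, float, float]
    adjusted_point_mm: tuple[float, float, float]


@dataclass(frozen=True)
class CropBox:
    """A physical axis-aligned box and its voxel realization on one grid."""

    center_mm: tuple[float, float, float]
    extent_mm: tuple[float, float, float]
    voxel_start: tuple[int, int, int]   # half-open [start, stop), may exceed grid
    voxel_stop: tuple[int, int, int]

    @property
    def voxel_shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.voxel_start, self.voxel_stop))


def find_root_point(aorta_mask: np.ndarray, lv_mask: np.ndarray, spacing, origin=(0.0, 0.0, 0.0),
                    offset_mm=DEFAULT_OFFSET_MM, max_dilation: int = 3) -> RootPoint:
    """Locate the aorta/LV contact centroid in world coordinates.

    When the masks share voxels the literal intersection is used.  Otherwise
    the contact set is the aorta voxels whose 1-voxel dilation touches the
    LV, union the symmetric LV-side set, with the dilation radius grown up
    to ``max_dilation`` voxels for abutting-but-separated segmentations.
    """
    aorta_mask = np.asarray(aorta_mask, dtype=bool)
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if aorta_mask.shape != lv_mask.shape:
        raise ValueError("aorta and LV masks must share one grid")
    if not aorta_mask.any() or not lv_mask.any():
        raise ValueError("aorta and LV masks must both be non-empty")

    contact = aorta_mask & lv_mask
    if not contact.any():
        struct = ndimage.generate_binary_structure(3, 1)
        for radius in range(1, max_dilation + 1):
            da = ndimage.binary_dilation(aorta_mask, struct, iterations=radius)
            dl = ndimage.binary_dilation(lv_mask, struct, iterations=radius)
            contact = (aorta_mask & dl) | (lv_mask & da)
            if contact.any():
                break
        else:
            raise ValueError(
                f"no aorto-ventricular contact within a dilation radius of {max_dilation} voxels"
            )

    centroid_idx = np.array(np.nonzero(contact), dtype=float).mean(axis=1)
    point = np.asarray(origin, dtype=float) + centroid_idx * np.asarray(spacing, dtype=float)
    adjusted = point + np.asarray(offset_mm, dtype=float)
    return RootPoint(tuple(point), tuple(adjusted))


def compute_crop_box(root: RootPoint, grid: ImageVolume, extent_mm=DEFAULT_EXTENT_MM) -> CropBox:
    """Voxel realization of the fixed box centered on the adjusted root point.

    Half-open index ranges are rounded outward by at most one voxel per face
    and may extend beyond the image; :func:`crop_volume` pads those parts.
    """
    extent = np.asarray(extent_mm, dtype=float)
    if np.any(extent <= 0):
        raise ValueError("extent_mm must be strictly positive")
    center = np.asarray(root.adjusted_point_mm, dtype=float)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    lo_idx = (center - extent / 2.0 - origin) / spacing
    start = np.floor(lo_idx + 1e-6).astype(int)
    n_vox = np.ceil(extent / spacing - 1e-6).astype(int)
    stop = start + n_vox
    return CropBox(tuple(center), tuple(extent), tuple(int(a) for a in start),
                   tuple(int(b) for b in stop))


def crop_volume(volume: ImageVolume, box: CropBox, pad_value: float = DEFAULT_PAD_HU) -> ImageVolume:
    """Extract the box from a volume, padding out-of-field voxels.

    The output origin is updated so the crop stays registered in world space.
    """
    start = np.asarray(box.voxel_start)
    stop = np.asarray(box.voxel_stop)
    shape = np.asarray(volume.shape)
    if np.any(stop <= 0) or np.any(start >= shape):
        raise ValueError("crop box lies entirely outside the image")
    out = np.full(tuple(stop - start), pad_value, dtype=volume.data.dtype)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(stop, shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = (
        volume.data[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]]
    )
    new_origin = np.asarray(volume.origin) + start * np.asarray(volume.spacing)
    return ImageVolume(out, spacing=volume.spacing, origin=tuple(float(o) for o in new_origin))


def naive_segment(volume: ImageVolume, contrast_range=(280.0, 600.0),
                  muscle_range=(55.0, 110.0), min_voxels: int = 50) -> LabelMap:
    """Rough threshold segmentation of phantom images for cropping.

    The contrast blood pool (aorta + LV cavity, which touch at the root) is
    thresholded and split at its narrow aorto-mitral neck by erosion; the
    two marker components are grown back over the blood pool by watershed
    and assigned aorta (smaller in-plane footprint, higher centroid) vs LV
    cavity.  Myocardium is the largest muscle-range component.  This is a
    phantom-only stand-in for a real segmentation model and is documented
    as such; only rough masks are needed to place the crop box.
    """
    data = volume.data.astype(np.float32)
    # median filter knocks down HU noise before thresholding
    smooth = ndimage.median_filter(data, size=3)
    blood = smooth >= contrast_range[0]
    blood &= smooth <= contrast_range[1] + 200.0  # generous ceiling
    lab, n = ndimage.label(blood)
    if n == 0:
        raise ValueError("no contrast-range component found; is the volume in HU?")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    pool = lab == (1 + int(np.argmax(sizes)))
    if pool.sum() < min_voxels:
        raise ValueError("no contrast-range component found; is the volume in HU?")

    # split the pool at its neck: erode until >= 2 sizeable components appear
    markers = None
    eroded = pool
    for _ in range(12):
        eroded = ndimage.binary_erosion(eroded)
        lab_e, n_e = ndimage.label(eroded)
        if n_e >= 2:
            sizes_e = ndimage.sum_labels(np.ones_like(lab_e), lab_e, index=np.arange(1, n_e + 1))
            keep = np.argsort(sizes_e)[-2:] + 1
            if sizes_e[keep - 1].min() > min_voxels:
                markers = np.where(np.isin(lab_e, keep), lab_e, 0)
                markers = (markers == keep[0]) * 1 + (markers == keep[1]) * 2
                break
    out = np.zeros(volume.shape, dtype=np.int16)
    if markers is None:
        # no split found: call the whole pool aorta (cropping still works)
        out[pool] = Label.AORTA
    else:
        grown = watershed(-ndimage.distance_transform_edt(pool, sampling=volume.spacing),
                          markers=markers, mask=pool)
        zc = [ndimage.center_of_mass(grown == k)[2] for k in (1, 2)]
        aorta_k = 1 + int(np.argmax(zc))       # aorta sits superior to the LV
        out[grown == aorta_k] = Label.AORTA
        out[(grown > 0) & (grown != aorta_k)] = Label.LV_CAVITY

    muscle = (smooth >= muscle_range[0]) & (smooth <= muscle_range[1])
    lab_m, n_m = ndimage.label(muscle)
    if n_m:
        sizes_m = ndimage.sum_labels(np.ones_like(lab_m), lab_m, index=np.arange(1, n_m + 1))
        myo = lab_m == (1 + int(np.argmax(sizes_m)))
        out[myo & (out == 0)] = Label.LV_MYOCARDIUM
    return LabelMap(out, spacing=volume.spacing, origin=volume.origin)


def crop_case(volume: ImageVolume, labels: LabelMap, extent_mm=DEFAULT_EXTENT_MM,
              offset_mm=DEFAULT_OFFSET_MM, pad_value: float = DEFAULT_PAD_HU) -> ImageVolume:
    """Root-point + box + crop in one step from an image and its label map."""
    root = find_root_point(labels.mask(Label.AORTA), labels.mask(Label.LV_CAVITY),
                           spacing=labels.spacing, origin=labels.origin, offset_mm=offset_mm)
    box = compute_crop_box(root, volume, extent_mm=extent_mm)
    return crop_volume(volume, box, pad_value=pad_value)
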