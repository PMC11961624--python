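"""Deterministic normalization of cropped volumes into network inputs.

Cropped HU volumes are (1) spline-resampled to fixed grid dimensions,
(2) clipped to [-1024, 1024] HU, (3) discretized into 256 integer levels and
(4) min-max scaled to [0, 1].  The published target grid is 215 x 215 x 85;
smaller grids are used for CPU-scale experiments via ``target_dims``.

The "256 levels" phrasing is resolved as integer levels 0..255 with the
upper clip edge mapped to level 255 (standard 8-bit convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

__all__ = [
    "PreprocessConfig",
    "resample",
    "clip_hu",
    "discretize",
    "minmax_normalize",
    "preprocess_pipeline",
    "CTPreprocessor",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_dims: tuple[int, int, int] = (215, 215, 85)
    hu_clip: tuple[float, float] = (-1024.0, 1024.0)
    n_levels: int = 256
    spline_order: int = 3

    def __post_init__(self) -> None:
        if self.hu_clip[0] >= self.hu_clip[1]:
            raise ValueError("hu_clip must satisfy lo < hi")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if any(int(d) < 2 for d in self.target_dims):
            raise ValueError("target_dims must all be >= 2")
        if not 0 <= self.spline_order <= 5:
            raise ValueError("spline_order must be in 0..5")


def resample(volume: ImageVolume, target_dims, spline_order: int = 3) -> ImageVolume:
    """Spline-resample to ``target_dims`` voxels, preserving physical extent.

    Output spacing is ``shape * spacing / target_dims`` per axis, so the
    grid covers the same physical field of view at a new resolution.
    """
    target = tuple(int(d) for d in target_dims)
    if any(d < 2 for d in target):
        raise ValueError("target dimensions must all be >= 2")
    shape = np.asarray(volume.shape, dtype=float)
    new_spacing = shape * np.asarray(volume.spacing) / np.asarray(target, dtype=float)
    if volume.shape == target:
        data = volume.data.copy()
    else:
        zoom = np.asarray(target, dtype=float) / shape
        data = ndimage.zoom(volume.data.astype(np.float32), zoom, order=spline_order,
                            mode="nearest", grid_mode=True)
        data = data[: target[0], : target[1], : target[2]]
    return ImageVolume(data, spacing=tuple(float(s) for s in new_spacing), origin=volume.origin)


def clip_hu(volume: ImageVolume, lo: float = -1024.0, hi: float = 1024.0) -> ImageVolume:
    if lo >= hi:
        raise ValueError("clip bounds must satisfy lo < hi")
    return ImageVolume(np.clip(volume.data, lo, hi), spacing=volume.spacing, origin=volume.origin)


def discretize(volume: ImageVolume, n_levels: int = 256,
               hu_clip: tuple[float, float] = (-1024.0, 1024.0)) -> ImageVolume:
    """Map clipped HU values to integer levels 0..n_levels-1.

    level(v) = floor((v - lo) / (hi - lo) * n_levels), with v = hi sent to
    the top level.  Raises if the input was not clipped first.
    """
    lo, hi = hu_clip
    data = np.asarray(volume.data)
    if data.min() < lo or data.max() > hi:
        raise ValueError(f"input must be clipped to [{lo}, {hi}] before discretization")
    levels = np.floor((data.astype(np.float64) - lo) / (hi - lo) * n_levels)
    levels = np.minimum(levels, n_levels - 1).astype(np.int32)
    return ImageVolume(levels, spacing=volume.spacing, origin=volume.origin)


def minmax_normalize(volume: ImageVolume) -> np.ndarray:
    """Per-volume (v - min) / (max - min); constant volumes map to zeros."""
    data = volume.data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros_like(data, dtype=np.float32)
    return (data - lo) / (hi - lo)


def preprocess_pipeline(volume: ImageVolume, config: PreprocessConfig | None = None) -> np.ndarray:
    """resample -> clip -> discretize -> min-max; returns a [0,1] tensor."""
    cfg = config or PreprocessConfig()
    vol = resample(volume, cfg.target_dims, cfg.spline_order)
    vol = clip_hu(vol, *cfg.hu_clip)
    vol = discretize(vol, cfg.n_levels, cfg.hu_clip)
    return minmax_normalize(vol)


class CTPreprocessor:
    """Stateless scikit-learn style transformer over the preprocessing chain.

    ``transform`` accepts a list of :class:`ImageVolume` (or a 4D array
    treated as stacked unit-spacing volumes) and returns an array of shape
    ``(n, *target_dims)`` in [0, 1].
    """

    def __init__(self, target_dims=(215, 215, 85), hu_clip=(-1024.0, 1024.0),
                 n_levels: int = 256, spline_order: int = 3):
        self.target_dims = tuple(target_dims)
        self.hu_clip = tuple(hu_clip)
        self.n_levels = n_levels
        self.spline_order = spline_order

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(self.target_dims, self.hu_clip, self.n_levels, self.spline_order)

    def fit(self, X, y=None):
        self._config()  # validate parameters
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        cfg = self._config()
        vols = [x if isinstance(x, ImageVolume) else ImageVolume(np.asarray(x)) for x in X]
        return np.stack([preprocess_pipeline(v, cfg) for v in vols])

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"target_dims": self.target_dims, "hu_clip": self.hu_clip,
                "n_levels": self.n_levels, "spline_order": self.spline_order}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self
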