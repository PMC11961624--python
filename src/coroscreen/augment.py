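"""Training-time augmentation of normalized [0, 1] input tensors.

Beyond generic intensity perturbations (noise, blur, gamma contrast) two
CT acquisition artifacts are emulated:

* cardiac motion, as a convex ghost sum of the tensor with small random
  rigid shifts (the first ghost is unshifted);
* the step ("step-and-shoot") artifact of non-helical scanners, as a rigid
  in-plane translation of all slices above a random table position.

Transforms are applied independently with per-transform probabilities in
the fixed order contrast -> blur -> noise -> motion -> step; every
transform maps [0,1] tensors to [0,1] tensors of the same shape and with
zero magnitude or probability is an exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentationConfig",
    "add_noise",
    "blur",
    "adjust_contrast",
    "simulate_motion",
    "simulate_step_artifact",
    "augment",
]


@dataclass
class AugmentationConfig:
    p_noise: float = 0.3
    p_blur: float = 0.3
    p_contrast: float = 0.3
    p_motion: float = 0.2
    p_step: float = 0.2
    noise_sigma: float = 0.03
    blur_sigma_mm: float = 1.0
    contrast_gamma_range: tuple[float, float] = (0.7, 1.4)
    motion_n_ghosts: int = 3
    motion_max_shift_mm: float = 3.0
    motion_weights: tuple = (0.6, 0.25, 0.15)
    step_axis: int = 2
    step_max_shift_mm: float = 3.0

    def validate(self) -> None:
        for name in ("p_noise", "p_blur", "p_contrast", "p_motion", "p_step"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.noise_sigma < 0 or self.blur_sigma_mm < 0:
            raise ValueError("sigmas must be >= 0")
        lo, hi = self.contrast_gamma_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("contrast_gamma_range must be positive with lo <= hi")
        if self.motion_n_ghosts < 1:
            raise ValueError("motion_n_ghosts must be >= 1")
        w = np.asarray(self.motion_weights[: self.motion_n_ghosts], dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("motion_weights must be non-negative and sum to 1")


def add_noise(tensor: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian intensity noise, re-clipped to [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return tensor
    out = tensor + rng.normal(0.0, sigma, size=tensor.shape).astype(tensor.dtype)
    return np.clip(out, 0.0, 1.0)


def blur(tensor: np.ndarray, sigma_mm: float, spacing_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Gaussian smoothing with a physical-units kernel."""
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return tensor
    sigma_vox = sigma_mm / np.asarray(spacing_mm, dtype=float)
    return ndimage.gaussian_filter(tensor, sigma=sigma_vox, mode="nearest")


def adjust_contrast(tensor: np.ndarray, gamma: float) -> np.ndarray:
    """Gamma contrast v**gamma on the [0, 1] scale."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if gamma == 1.0:
        return tensor
    return np.power(tensor, gamma, dtype=tensor.dtype if tensor.dtype.kind == "f" else np.float32)


def _rigid_shift(tensor: np.ndarray, shift_vox) -> np.ndarray:
    if not np.any(np.asarray(shift_vox)):
        return tensor
    return ndimage.shift(tensor, shift_vox, order=1, mode="constant", cval=0.0)


def simulate_motion(tensor: np.ndarray, n_ghosts: int, max_shift_mm: float, weights,
                    rng: np.random.Generator, spacing_mm=(1.0, 1.0, 1.0),
                    shifts_mm=None) -> np.ndarray:
    """Ghosting from cardiac motion: convex sum of randomly shifted copies.

    The first ghost is the unshifted tensor; the remaining ``n_ghosts - 1``
    are shifted by random displacements of norm <= ``max_shift_mm``.
    ``shifts_mm`` (one 3-vector per ghost) overrides the random draws.
    """
    if n_ghosts < 1:
        raise ValueError("n_ghosts must be >= 1")
    w = np.asarray(weights, dtype=float)[:n_ghosts]
    if len(w) != n_ghosts or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative, one per ghost, summing to 1")
    spacing = np.asarray(spacing_mm, dtype=float)
    if shifts_mm is None:
        shifts = [np.zeros(3)]
        for _ in range(1, n_ghosts):
            direction = rng.normal(size=3)
            direction /= max(np.linalg.norm(direction), 1e-12)
            shifts.append(direction * max_shift_mm * rng.uniform(0.0, 1.0))
    else:
        shifts = [np.asarray(s, dtype=float) for s in shifts_mm]
        if len(shifts) != n_ghosts:
            raise ValueError("shifts_mm must provide one displacement per ghost")
    out = w[0] * _rigid_shift(tensor, shifts[0] / spacing)
    for k in range(1, n_ghosts):
        if w[k] > 0:
            out = out + w[k] * _rigid_shift(tensor, shifts[k] / spacing)
    return out.astype(tensor.dtype, copy=False) if np.issubdtype(tensor.dtype, np.floating) else out


def simulate_step_artifact(tensor: np.ndarray, slab_axis: int, max_shift_mm: float,
                           rng: np.random.Generator, spacing_mm=(1.0, 1.0, 1.0),
                           s: int | None = None, offset_mm=None) -> np.ndarray:
    """Table-position misregistration: slices >= s shifted rigidly in-plane.

    ``s`` (slab start slice) and ``offset_mm`` (in-plane 2-vector) override
    the random draws.
    """
    if tensor.shape[slab_axis] < 2:
        raise ValueError("need at least 2 slices along the slab axis")
    if s is None:
        s = int(rng.integers(0, tensor.shape[slab_axis] + 1))
    inplane_axes = [a for a in range(3) if a != slab_axis]
    spacing = np.asarray(spacing_mm, dtype=float)
    if offset_mm is None:
        angle = rng.uniform(0, 2 * np.pi)
        r_mm = max_shift_mm * rng.uniform(0.0, 1.0)
        offset_mm = (r_mm * np.cos(angle), r_mm * np.sin(angle))
    offset = np.zeros(3)
    offset[inplane_axes[0]] = offset_mm[0] / spacing[inplane_axes[0]]
    offset[inplane_axes[1]] = offset_mm[1] / spacing[inplane_axes[1]]
    if (max_shift_mm == 0 and offset_mm is None) or not np.any(offset) or s >= tensor.shape[slab_axis]:
        return tensor
    sl = [slice(None)] * 3
    sl[slab_axis] = slice(s, None)
    out = tensor.copy()
    out[tuple(sl)] = _rigid_shift(tensor[tuple(sl)], offset)
    return out


def augment(tensor: np.ndarray, config: AugmentationConfig, rng: np.random.Generator,
            spacing_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Apply the configured transforms stochastically in fixed order."""
    config.validate()
    out = tensor
    if config.p_contrast > 0 and rng.random() < config.p_contrast:
        gamma = rng.uniform(*config.contrast_gamma_range)
        out = adjust_contrast(out, gamma)
    if config.p_blur > 0 and rng.random() < config.p_blur:
        out = blur(out, config.blur_sigma_mm, spacing_mm)
    if config.p_noise > 0 and rng.random() < config.p_noise:
        out = add_noise(out, config.noise_sigma, rng)
    if config.p_motion > 0 and rng.random() < config.p_motion:
        out = simulate_motion(out, config.motion_n_ghosts, config.motion_max_shift_mm,
                              config.motion_weights, rng, spacing_mm)
    if config.p_step > 0 and rng.random() < config.p_step:
        out = simulate_step_artifact(out, config.step_axis, config.step_max_shift_mm,
                                     rng, spacing_mm)
    return out
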