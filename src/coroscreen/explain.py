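"""Grad-CAM++ volumetric saliency and latent-feature maps.

Grad-CAM++ weights each channel of a chosen stage's activation by the
spatially summed, pixel-weighted positive gradients of the (exponentiated)
class score, using the closed-form higher-order coefficients valid for
piecewise-linear networks.  The rectified weighted activation sum is
trilinearly upsampled to the input grid and min-max normalized.

Embeddings are the global-average-pooled features entering the classifier
head; they are a pure function of image and weights (labels are attached
only as plotting metadata), and can be projected to 2D with t-SNE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .nn import SEResNet3D

__all__ = ["SaliencyMap", "EmbeddingSet", "gradcam_pp", "extract_embeddings", "tsne_map"]

log = logging.getLogger(__name__)


@dataclass
class SaliencyMap:
    values: np.ndarray            # [0,1], aligned to the input tensor grid
    source_block: int

    def __post_init__(self):
        v = np.asarray(self.values)
        if not np.isfinite(v).all() or (v.size and (v.min() < 0 or v.max() > 1)):
            raise ValueError("saliency values must be finite and in [0, 1]")
        self.values = v


@dataclass
class EmbeddingSet:
    case_ids: list
    features: np.ndarray          # (n, feature_width)
    labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    coords2d: np.ndarray | None = None


def gradcam_pp(model: SEResNet3D, input_tensor: np.ndarray, block_index: int = 1,
               target_class: int = 1) -> SaliencyMap:
    """Grad-CAM++ map for one [0,1] volume at a given stage (0-based).

    ``target_class=1`` explains the positive (anomaly/right/high) logit;
    0 explains its complement.  A network with zero gradient everywhere
    (e.g. constant activations) yields an all-zero map, with a warning.
    """
    x = np.asarray(input_tensor, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if not 0 <= block_index < len(model.stages):
        raise ValueError(f"block_index must be in [0, {len(model.stages) - 1}]")
    logit = model.forward(x, train=False)[0]
    sign = 1.0 if target_class == 1 else -1.0
    model.backward(np.array([sign]), retain_stage_grads=True)
    act = model.stage_outputs[block_index][0]          # (C, d, h, w)
    grad = model.stage_grads[block_index][0]

    g2 = grad * grad
    g3 = g2 * grad
    denom = 2.0 * g2 + np.sum(act * g3, axis=(1, 2, 3), keepdims=True)
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    # positive gradients of the exponentiated score; exp(logit) is a common
    # positive factor and cancels under the final min-max normalization
    weights = np.sum(alpha * np.maximum(grad, 0.0), axis=(1, 2, 3))
    cam = np.maximum(np.tensordot(weights, act, axes=1), 0.0)

    if not np.any(cam):
        log.warning("Grad-CAM++ gradient is zero everywhere; returning an all-zero map")
        return SaliencyMap(np.zeros(x.shape[1:], dtype=np.float32), block_index)

    zoom = np.asarray(x.shape[1:]) / np.asarray(cam.shape)
    up = ndimage.zoom(cam, zoom, order=1, mode="nearest", grid_mode=True)
    up = up[: x.shape[1], : x.shape[2], : x.shape[3]]
    lo, hi = float(up.min()), float(up.max())
    up = (up - lo) / (hi - lo) if hi > lo else np.zeros_like(up)
    return SaliencyMap(up.astype(np.float32), block_index)


def extract_embeddings(model: SEResNet3D, tensors, case_ids=None, labels=None,
                       metadata=None, batch_size: int = 16) -> EmbeddingSet:
    """Deterministic last-pre-head features for a stack of input tensors."""
    x = np.asarray(tensors, dtype=np.float32)
    feats = []
    for i in range(0, len(x), batch_size):
        model.forward(x[i:i + batch_size], train=False)
        feats.append(model.features.copy())
    features = np.concatenate(feats) if feats else np.empty((0, model.feature_width))
    ids = list(case_ids) if case_ids is not None else [f"img-{i}" for i in range(len(x))]
    return EmbeddingSet(ids, features, None if labels is None else np.asarray(labels),
                        dict(metadata or {}))


def tsne_map(embeddings: EmbeddingSet, perplexity: float = 30.0, seed: int = 0,
             pca_dims: int = 50) -> np.ndarray:
    """2D t-SNE of the latent features; deterministic given seed.

    Features wider than ``pca_dims`` are PCA-reduced first.  Requires
    n_points > 3 * perplexity.
    """
    feats = np.asarray(embeddings.features, dtype=np.float64)
    n = len(feats)
    if n <= 3 * perplexity:
        raise ValueError(f"t-SNE needs more than 3*perplexity={3 * perplexity:.0f} points, got {n}")
    if feats.shape[1] > pca_dims:
        feats = PCA(n_components=pca_dims, random_state=seed).fit_transform(feats)
    coords = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                  init="pca").fit_transform(feats)
    embeddings.coords2d = coords
    return coords
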