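"""3D squeeze-and-excitation residual classifier.

The architecture family: a strided convolutional stem, ``n_stages`` stages
of SE-residual blocks (channel width doubling and spatial downsampling at
each stage transition), global average pooling and a single-logit head.
``predict_proba`` applies the sigmoid, so outputs live strictly in (0, 1).

The publication-scale preset uses 4 stages with a (3, 8, 36, 3) bottleneck
pattern (the SE-ResNet-152 family adapted to 3D); `layer_count` reports the
realized depth counting main-path convolutions plus the classifier head.
A 2-stage basic-block ``tiny`` preset keeps training CPU-friendly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import logging

from .layers import BatchNorm3d, Conv3d, GlobalAvgPool, Linear, ReLU, SEGate

log = logging.getLogger(__name__)

__all__ = ["NetworkConfig", "SEResNet3D", "build_network", "layer_count",
           "apply_se_recalibration", "bce_with_logits", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    n_stages: int = 4
    blocks_per_stage: tuple = (3, 8, 36, 3)
    block_type: str = "bottleneck"          # or "basic"
    base_channels: int = 64
    se_reduction: int = 16
    input_dims: tuple = (215, 215, 85)
    n_outputs: int = 1
    stem_stride: int = 2

    def __post_init__(self):
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if len(self.blocks_per_stage) != self.n_stages:
            raise ValueError("blocks_per_stage must have one count per stage")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")
        if self.block_type not in ("basic", "bottleneck"):
            raise ValueError("block_type must be 'basic' or 'bottleneck'")
        if self.n_outputs != 1:
            raise ValueError("single-logit binary head only")

    @classmethod
    def tiny(cls, input_dims=(32, 32, 24)) -> "NetworkConfig":
        return cls(n_stages=2, blocks_per_stage=(1, 1), block_type="basic",
                   base_channels=8, se_reduction=4, input_dims=tuple(input_dims))

    @classmethod
    def paper(cls) -> "NetworkConfig":
        return cls()


def layer_count(config: NetworkConfig) -> int:
    """Weighted main-path layers: stem conv + block convs (+ head fc)."""
    per_block = 3 if config.block_type == "bottleneck" else 2
    return 1 + per_block * int(sum(config.blocks_per_stage)) + 1


class _SEBlock:
    """One SE-residual block (basic 2-conv or bottleneck 3-conv)."""

    def __init__(self, rng, c_in, c_out, stride, block_type, se_reduction):
        self.downsample = None
        if block_type == "basic":
            self.convs = [Conv3d(rng, c_in, c_out, 3, stride), Conv3d(rng, c_out, c_out, 3, 1)]
        else:
            mid = max(c_out // 4, 1)
            self.convs = [Conv3d(rng, c_in, mid, 1, 1, pad=0),
                          Conv3d(rng, mid, mid, 3, stride),
                          Conv3d(rng, mid, c_out, 1, 1, pad=0)]
        self.bns = [BatchNorm3d(c.c_out) for c in self.convs]
        self.relus = [ReLU() for _ in self.convs]
        self.se = SEGate(rng, c_out, se_reduction)
        if stride != 1 or c_in != c_out:
            self.downsample = (Conv3d(rng, c_in, c_out, 1, stride, pad=0), BatchNorm3d(c_out))
        self.out_relu = ReLU()

    def layers(self):
        out = list(self.convs) + self.bns + [self.se]
        if self.downsample:
            out += list(self.downsample)
        return out

    def forward(self, x, train=False):
        h = x
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            h = bn.forward(conv.forward(h, train), train)
            if i < len(self.convs) - 1:
                h = self.relus[i].forward(h, train)
        h = self.se.forward(h, train)
        if self.downsample:
            skip = self.downsample[1].forward(self.downsample[0].forward(x, train), train)
        else:
            skip = x
        return self.out_relu.forward(h + skip, train)

    def backward(self, dy):
        dsum = self.out_relu.backward(dy)
        if self.downsample:
            dx_skip = self.downsample[0].backward(self.downsample[1].backward(dsum))
        else:
            dx_skip = dsum
        dh = self.se.backward(dsum)
        for i in range(len(self.convs) - 1, -1, -1):
            if i < len(self.convs) - 1:
                dh = self.relus[i].backward(dh)
            dh = self.convs[i].backward(self.bns[i].backward(dh))
        return dh + dx_skip


class SEResNet3D:
    """The classifier network; exposes stage activations for saliency."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        self.stem = Conv3d(rng, 1, c, 3, config.stem_stride)
        self.stem_bn = BatchNorm3d(c)
        self.stem_relu = ReLU()
        self.stages = []
        c_in = c
        dims = np.asarray(config.input_dims, dtype=int)
        dims = -(-dims // config.stem_stride)
        for s in range(config.n_stages):
            c_out = c * (2**s)
            blocks = []
            for b in range(config.blocks_per_stage[s]):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(_SEBlock(rng, c_in, c_out, stride, config.block_type,
                                       config.se_reduction))
                c_in = c_out
            if s > 0:
                if np.any(dims < 2):
                    raise ValueError(
                        f"input_dims {config.input_dims} too small for {config.n_stages} "
                        f"stages of downsampling")
                dims = -(-dims // 2)
            self.stages.append(blocks)
        self.pool = GlobalAvgPool()
        self.head = Linear(rng, c_in, config.n_outputs)
        self.feature_width = c_in
        self.stage_outputs: list = []
        self.stage_grads: list = []

    # -- bookkeeping -------------------------------------------------------
    def layers(self):
        out = [self.stem, self.stem_bn]
        for blocks in self.stages:
            for b in blocks:
                out += b.layers()
        out.append(self.head)
        return out

    @property
    def layer_count(self) -> int:
        return layer_count(self.config)

    def zero_grad(self):
        for layer in self.layers():
            layer.zero_grad()

    def parameters(self):
        for i, layer in enumerate(self.layers()):
            for name, p in layer.params.items():
                yield f"{i}.{name}", p, layer.grads[name]

    # -- compute -----------------------------------------------------------
    def forward(self, x, train: bool = False):
        """x: (N, D, H, W) or (N, 1, D, H, W) in [0,1] -> logits (N,)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:
            x = x[:, None]
        h = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x, train), train), train)
        self.stage_outputs = []
        for blocks in self.stages:
            for b in blocks:
                h = b.forward(h, train)
            self.stage_outputs.append(h)
        self.features = self.pool.forward(h, train)
        logits = self.head.forward(self.features, train)
        return logits[:, 0]

    def backward(self, dlogits, retain_stage_grads: bool = False):
        dy = self.head.backward(np.asarray(dlogits, dtype=np.float32)[:, None])
        dh = self.pool.backward(dy)
        self.stage_grads = [None] * len(self.stages)
        for s in range(len(self.stages) - 1, -1, -1):
            if retain_stage_grads:
                self.stage_grads[s] = dh
            for b in reversed(self.stages[s]):
                dh = b.backward(dh)
        return self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(dh)))

    def predict_proba(self, x, batch_size: int = 16) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            out.append(1.0 / (1.0 + np.exp(-logits)))
        return np.concatenate(out) if out else np.empty(0)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers()):
            for name, p in layer.params.items():
                state[f"{i}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm3d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict, skip_head: bool = False) -> None:
        layers = self.layers()
        head_idx = len(layers) - 1
        for i, layer in enumerate(layers):
            if skip_head and i == head_idx:
                continue
            for name in layer.params:
                src = state[f"{i}.{name}"]
                if src.shape != layer.params[name].shape:
                    raise ValueError(f"architecture mismatch at layer {i} ({name}): "
                                     f"{src.shape} vs {layer.params[name].shape}")
                layer.params[name] = src.copy()
            if isinstance(layer, BatchNorm3d):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()


def build_network(config: NetworkConfig, seed: int = 0) -> SEResNet3D:
    """Instantiate a Kaiming-initialized network; deterministic given seed."""
    model = SEResNet3D(config, seed=seed)
    log.info("built %d-stage %s SE-ResNet3D with %d weighted layers",
             config.n_stages, config.block_type, model.layer_count)
    return model


def apply_se_recalibration(feature_block: np.ndarray, se_weights: np.ndarray) -> np.ndarray:
    """Channel-wise gating: output channel c = gate_c * input channel c.

    ``feature_block`` is (C, D, H, W) or (N, C, D, H, W); one gate in [0,1]
    per channel.
    """
    block = np.asarray(feature_block)
    gates = np.asarray(se_weights, dtype=block.dtype if block.dtype.kind == "f" else np.float32)
    ch_axis = 0 if block.ndim == 4 else 1
    if gates.shape != (block.shape[ch_axis],):
        raise ValueError(f"expected {block.shape[ch_axis]} gate weights, got {gates.shape}")
    shape = [1] * block.ndim
    shape[ch_axis] = -1
    return block * gates.reshape(shape)


def bce_with_logits(logits: np.ndarray, y: np.ndarray):
    """Mean binary cross entropy and its gradient w.r.t. the logits."""
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    p = 1.0 / (1.0 + np.exp(-logits))
    return loss, ((p - y) / len(y)).astype(np.float32)


def save_checkpoint(model: SEResNet3D, path) -> None:
    """Portable weights (.npz) + JSON config sidecar."""
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in vars(model.config).items()}
    path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> SEResNet3D:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    cfg = NetworkConfig(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in cfg_raw.items()})
    model = SEResNet3D(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
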