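"""Restoration architectures: a residual U-Net for super-resolution and
denoising, plus the bilinear-upscaling control.

The network follows the classic encoder/decoder layout: encoder levels
of residual blocks progressively halve the spatial size while widening
channels, decoder levels upsample back with skip connections from the
matching encoder level, and a sub-pixel (pixel-shuffle) head realizes
the super-resolution factor.  The head is initialized near zero and the
output is added to a bilinear upscale of the input, so an untrained
model starts at the control and learns a residual correction.

``scale = 1`` configures the same network for pure denoising: output
geometry equals input geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .nn import Tensor, concat, Module, Conv2d, BatchNorm2d, ReLU, Sequential

__all__ = ["ModelSpec", "ResUNet", "build_resunet",
           "count_trainable_layers", "bilinear_control",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    Defaults give a 4-level encoder with a (3, 4, 6, 3) residual-block
    ladder and 64 base channels — a ResNet-depth encoder.  Tests and
    desk-scale runs use much smaller configurations.
    """

    in_channels: int = 1
    out_channels: int = 1
    scale: int = 4
    encoder_blocks: tuple[int, ...] = (3, 4, 6, 3)
    base_width: int = 64

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.scale < 1 or (self.scale & (self.scale - 1)):
            raise ValueError(f"scale must be a power of 2, got {self.scale}")
        if len(self.encoder_blocks) < 2:
            raise ValueError("at least 2 resolution levels are required")
        if self.base_width < 1:
            raise ValueError("base_width must be positive")

    @property
    def levels(self) -> int:
        return len(self.encoder_blocks)

    @property
    def divisibility(self) -> int:
        """Input sides must be divisible by this factor."""
        return 2 ** (self.levels - 1)


class ResidualBlock(Module):
    """conv-BN-ReLU-conv-BN with identity shortcut, ReLU after the add."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.conv1 = Conv2d(width, width, 3, rng)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, rng)
        self.bn2 = BatchNorm2d(width)

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + x).relu()


class ResUNet(Module):
    """Residual U-Net mapping (N, C, H, W) to (N, C', scale*H, scale*W)."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        widths = [spec.base_width * 2 ** i for i in range(spec.levels)]
        self.stem = Conv2d(spec.in_channels, widths[0], 3, rng)
        self.enc_levels = [
            Sequential(*[ResidualBlock(widths[i], rng)
                         for _ in range(spec.encoder_blocks[i])])
            for i in range(spec.levels)]
        self.downs = [Conv2d(widths[i], widths[i + 1], 1, rng, padding=0)
                      for i in range(spec.levels - 1)]
        self.up_convs = [Conv2d(widths[i + 1], widths[i], 3, rng)
                         for i in reversed(range(spec.levels - 1))]
        self.fuse_convs = [Conv2d(2 * widths[i], widths[i], 3, rng)
                           for i in reversed(range(spec.levels - 1))]
        self.dec_blocks = [ResidualBlock(widths[i], rng)
                           for i in reversed(range(spec.levels - 1))]
        head_out = spec.out_channels * spec.scale * spec.scale
        # near-zero init: the model starts at the bilinear control and
        # learns a residual correction
        self.head = Conv2d(widths[0], head_out, 3, rng, weight_scale=1e-3)

    def forward(self, x: Tensor) -> Tensor:
        spec = self.spec
        n, c, h, w = x.shape
        if c != spec.in_channels:
            raise ValueError(f"expected {spec.in_channels} channels, got {c}")
        d = spec.divisibility
        if h % d or w % d:
            raise ValueError(
                f"input sides {(h, w)} must be divisible by {d} for a "
                f"{spec.levels}-level network")
        feats = self.stem(x).relu()
        skips = []
        for i in range(spec.levels):
            feats = self.enc_levels[i](feats)
            if i < spec.levels - 1:
                skips.append(feats)
                feats = self.downs[i](feats.avg_pool2d(2))
        for up, fuse, block, skip in zip(self.up_convs, self.fuse_convs,
                                         self.dec_blocks, reversed(skips)):
            feats = up(feats.upsample_nearest(2))
            feats = fuse(concat([feats, skip], axis=1)).relu()
            feats = block(feats)
        out = self.head(feats)
        if spec.scale > 1:
            out = out.pixel_shuffle(spec.scale)
        if spec.in_channels == spec.out_channels:
            skip_up = np.stack([
                np.stack([bilinear_control(x.data[b, ch], spec.scale)
                          for ch in range(c)]) for b in range(n)])
            out = out + Tensor(skip_up)
        return out

    def predict_array(self, lr: np.ndarray) -> np.ndarray:
        """Run a single 2-D image through the network in eval mode."""
        self.eval_mode()
        x = Tensor(np.asarray(lr, dtype=np.float64)[None, None])
        out = self(x).data[0, 0]
        self.train_mode()
        return np.clip(out, 0.0, 1.0)


def build_resunet(spec: ModelSpec, seed: int = 0) -> ResUNet:
    """Construct a seeded ResUNet; same spec and seed give identical
    parameter tensors."""
    return ResUNet(spec, seed=seed)


def count_trainable_layers(model: Module) -> int:
    """Number of parameter-bearing convolutional/linear layers.

    Convention: one count per distinct weight tensor of rank >= 2
    (convolution kernels); normalization scale/shift vectors are not
    counted as layers.
    """
    return sum(1 for p in model.parameters() if p.data.ndim >= 2)


def bilinear_control(lr: np.ndarray, scale: int) -> np.ndarray:
    """Bilinear upscaling by an integer factor — the no-learning control.

    Half-pixel-center alignment; ``scale = 1`` is the identity.  Every
    resize in the package (including the network's global skip branch)
    goes through this function so model and control share one
    interpolation convention.
    """
    if scale < 1:
        raise ValueError(f"scale must be >= 1, got {scale}")
    lr = np.asarray(lr, dtype=np.float64)
    if scale == 1:
        return lr.copy()
    out_shape = (lr.shape[0] * scale, lr.shape[1] * scale)
    return _sk_resize(lr, out_shape, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def save_checkpoint(model: ResUNet, path: str | Path) -> None:
    """Persist weights plus the architecture spec, so a checkpoint is
    self-describing."""
    path = Path(path)
    state = model.state_dict()
    spec = asdict(model.spec)
    spec["encoder_blocks"] = list(spec["encoder_blocks"])
    np.savez(path, __spec__=np.frombuffer(
        json.dumps(spec).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path, seed: int = 0) -> ResUNet:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        spec_json = bytes(data["__spec__"]).decode()
        spec_dict = json.loads(spec_json)
        spec_dict["encoder_blocks"] = tuple(spec_dict["encoder_blocks"])
        spec = ModelSpec(**spec_dict)
        model = ResUNet(spec, seed=seed)
        state = {k: data[k] for k in data.files if k != "__spec__"}
    model.load_state_dict(state)
    return model
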