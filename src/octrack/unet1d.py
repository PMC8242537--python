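"""Simplified 1D U-net for A-scan retinal layer segmentation.

The family has ``b`` contracting blocks (conv -> batch norm -> ReLU -> max
pool) and ``b`` expanding blocks (transposed conv -> optional skip
concatenation -> conv -> batch norm -> ReLU), a single convolution per block,
the same channel count everywhere, and a 1x1 convolution head collapsing to
the 8 layer classes.  The convolution kernel (default 15) is chosen so the
receptive field exceeds the 320-pixel input:

    r = s**b * (1 + 2*(k - 1)) - k

where s is the sampling size (max-pool and transposed-conv kernel), b the
number of blocks, and k the convolution kernel size.

Inputs are normalized per A-scan by division by the scan maximum, which keeps
the multiplicative speckle statistics scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .phantom import AScan, LabelMask, N_CLASSES

__all__ = [
    "UNetConfig",
    "SegmentationModel",
    "receptive_field",
    "build_model",
    "predict_mask",
    "normalize",
    "save_model",
    "load_model",
]


def receptive_field(k: int, s: int, b: int) -> int:
    """Receptive field in pixels of one output pixel of the b-block U-net."""
    if min(k, s, b) < 1:
        raise ValueError("k, s, b must all be >= 1")
    return s**b * (1 + 2 * (k - 1)) - k


@dataclass
class UNetConfig:
    n_blocks: int = 3
    n_channels: int = 12
    conv_kernel: int = 15
    sampling_size: int = 4
    skip_concat: bool = False
    n_classes: int = N_CLASSES
    input_length: int = 320

    def validate(self) -> None:
        if min(self.n_blocks, self.n_channels, self.conv_kernel,
               self.sampling_size, self.n_classes, self.input_length) < 1:
            raise ValueError("all UNetConfig fields must be positive")
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd")
        if self.input_length % self.sampling_size**self.n_blocks:
            raise ValueError(
                f"input_length {self.input_length} not divisible by "
                f"sampling_size**n_blocks = {self.sampling_size**self.n_blocks}"
            )

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.conv_kernel, self.sampling_size, self.n_blocks)


class SegmentationModel:
    """The network plus its configuration.  ``forward`` returns logits of
    shape ``(N, n_classes, input_length)``; ``backward`` propagates a loss
    gradient w.r.t. those logits through every layer."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.trained = False
        rng = np.random.default_rng(seed)
        C, k, s, b = (config.n_channels, config.conv_kernel,
                      config.sampling_size, config.n_blocks)
        self.down = []
        c_in = 1
        for _ in range(b):
            self.down.append({
                "conv": nn.Conv1d(c_in, C, k, rng),
                "bn": nn.BatchNorm1d(C),
                "relu": nn.ReLU(),
                "pool": nn.MaxPool1d(s),
            })
            c_in = C
        self.up = []
        for _ in range(b):
            conv_in = 2 * C if config.skip_concat else C
            self.up.append({
                "tconv": nn.ConvTranspose1d(C, C, s, rng),
                "conv": nn.Conv1d(conv_in, C, k, rng),
                "bn": nn.BatchNorm1d(C),
                "relu": nn.ReLU(),
            })
        self.head = nn.Conv1d(C, config.n_classes, 1, rng)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        h = x.astype(np.float32)
        for blk in self.down:
            h = blk["relu"].forward(blk["bn"].forward(blk["conv"].forward(h, train), train), train)
            skips.append(h if self.config.skip_concat else None)
            h = blk["pool"].forward(h, train)
        for blk, skip in zip(self.up, reversed(skips)):
            h = blk["tconv"].forward(h, train)
            if self.config.skip_concat:
                h = np.concatenate([skip, h], axis=1)
            h = blk["relu"].forward(blk["bn"].forward(blk["conv"].forward(h, train), train), train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        C = self.config.n_channels
        d = self.head.backward(dlogits.astype(np.float32))
        dskips = []
        for blk in reversed(self.up):
            d = blk["conv"].backward(blk["bn"].backward(blk["relu"].backward(d)))
            if self.config.skip_concat:
                dskips.append(d[:, :C])
                d = d[:, C:]
            else:
                dskips.append(None)
            d = blk["tconv"].backward(d)
        # dskips were collected while walking the up path backward, i.e. for
        # skips[0], skips[1], ...; the down path is walked deepest-first
        for blk, dskip in zip(reversed(self.down), reversed(dskips)):
            d = blk["pool"].backward(d)
            if dskip is not None:
                d = d + dskip
            d = blk["conv"].backward(blk["bn"].backward(blk["relu"].backward(d)))

    # -- bookkeeping --------------------------------------------------------

    def _layers(self):
        for blk in self.down:
            yield from (blk["conv"], blk["bn"])
        for blk in self.up:
            yield from (blk["tconv"], blk["conv"], blk["bn"])
        yield self.head

    def params(self) -> list[dict]:
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p["value"].size for p in self.params())

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, layer in enumerate(self._layers()):
            for j, p in enumerate(layer.params()):
                arrays[f"p{i}_{j}"] = p["value"]
            if isinstance(layer, nn.BatchNorm1d):
                arrays[f"p{i}_rm"] = layer.running_mean
                arrays[f"p{i}_rv"] = layer.running_var
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            for j, p in enumerate(layer.params()):
                p["value"][...] = arrays[f"p{i}_{j}"]
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = arrays[f"p{i}_rm"]
                layer.running_var[...] = arrays[f"p{i}_rv"]


def build_model(config: UNetConfig, seed: int = 0) -> SegmentationModel:
    """Construct an untrained model; raises if the config is inconsistent."""
    return SegmentationModel(config, seed=seed)


def normalize(intensity: np.ndarray) -> np.ndarray:
    """Per-A-scan max normalization; an all-zero scan stays zero."""
    x = np.asarray(intensity, dtype=np.float32)
    mx = x.max(axis=-1, keepdims=True)
    return np.where(mx > 0, x / np.maximum(mx, 1e-12), x)


def predict_logits(model: SegmentationModel, batch: np.ndarray) -> np.ndarray:
    """Inference on a normalized batch shaped (N, L); returns (N, C, L)."""
    return model.forward(normalize(batch)[:, None, :], train=False)


def predict_mask(model: SegmentationModel, ascan: AScan) -> LabelMask:
    """Argmax class per pixel for a single (cropped) A-scan."""
    L = model.config.input_length
    if len(ascan) != L:
        raise ValueError(f"A-scan length {len(ascan)} != model input length {L}")
    logits = predict_logits(model, ascan.intensity[None, :])
    return LabelMask(np.argmax(logits[0], axis=0))


def predict_masks(model: SegmentationModel, batch: np.ndarray) -> np.ndarray:
    """Argmax masks for a batch shaped (N, L) -> (N, L)."""
    return np.argmax(predict_logits(model, batch), axis=1)


def save_model(model: SegmentationModel, path: str | Path) -> None:
    """Checkpoint: NPZ with weights plus the YAML-serialized config."""
    path = Path(path)
    arrays = model.state_arrays()
    arrays["__config__"] = np.frombuffer(
        yaml.safe_dump(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> SegmentationModel:
    with np.load(Path(path)) as data:
        cfg = UNetConfig(**yaml.safe_load(bytes(data["__config__"]).decode()))
        model = SegmentationModel(cfg)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    model.trained = True
    return model
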