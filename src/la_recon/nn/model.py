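"""The 30-layer 3D residual encoder-decoder segmentation network.

Architecture (default width 8, 4 down-sampling levels, 5x5x5 kernels):

* encoder — per level, a residual group of 1-3 stride-1 convolutions
  (1, 2, 3, 3 convolutions at levels 0-3), each followed by batch
  normalization, PReLU and channel dropout; then a 2x2x2 stride-2
  convolution that halves each axis and doubles the width
  (8 -> 16 -> 32 -> 64 -> 128);
* a bottom residual group of 3 convolutions at width 128;
* decoder — per level, a 2x2x2 stride-2 transpose convolution, concatenation
  of the matching encoder feature (4 feature-forwarding points), and a
  residual conv group whose width decreases 64 -> 32 -> 16 -> 16;
* a final 1x1x1 convolution to 2 channels with a per-voxel softmax over
  {background, LA}.

The network is fully convolutional: any input shape works (odd extents are
zero-padded before each down-convolution and cropped again after the matching
up-convolution, so output shape always equals input shape).  Residual skips
use 1x1x1 projections exactly where a group changes channel count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..types import LAGeometry, PartialShell
from .layers import (
    BatchNorm3d,
    Conv3d,
    DownConv2x,
    Layer,
    Param,
    PReLU,
    ResidualBlock,
    Sequence,
    SpatialDropout,
    UpConv2x,
    softmax_backward,
    softmax_channels,
)

__all__ = ["NetworkConfig", "ResidualUNet3D", "build_network", "predict"]


@dataclass(frozen=True)
class NetworkConfig:
    """Width-scalable configuration of the segmentation network."""

    base_width: int = 8
    levels: int = 4
    kernel_size: int = 5
    dropout_rate: float = 0.5
    input_shape: tuple[int, int, int] = (128, 208, 88)

    def __post_init__(self) -> None:
        if self.base_width < 1 or self.levels < 1:
            raise ValueError("base_width and levels must be positive")
        if self.kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__ | {"input_shape": list(self.input_shape)}))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkConfig":
        d = json.loads(Path(path).read_text())
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


def _conv_unit(cin, cout, k, dropout, rng, name) -> list[Layer]:
    return [
        Conv3d(cin, cout, k, rng, name=name),
        BatchNorm3d(cout, name=f"{name}.bn"),
        PReLU(cout, name=f"{name}.prelu"),
        SpatialDropout(dropout, rng),
    ]


def _residual_group(cin, cout, n_convs, k, dropout, rng, name) -> ResidualBlock:
    layers: list[Layer] = []
    c = cin
    for j in range(n_convs):
        layers += _conv_unit(c, cout, k, dropout, rng, f"{name}.conv{j}")
        c = cout
    projection = None
    if cin != cout:
        projection = Conv3d(cin, cout, 1, rng, name=f"{name}.proj")
    return ResidualBlock(Sequence(layers), projection)


class ResidualUNet3D:
    """Fully convolutional residual encoder-decoder for LA segmentation."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng([int(seed) % (2**31), 1234])
        self.rng = rng
        L = config.levels
        w = config.base_width
        k = config.kernel_size
        p = config.dropout_rate

        self.enc_widths = [w * 2**i for i in range(L)]
        bottom_width = w * 2**L
        self.dec_widths = [max(w * 2**i, 2 * w) for i in range(L)]
        n_convs = [min(i + 1, 3) for i in range(L)]

        self.enc_blocks: list[ResidualBlock] = []
        self.downs: list[Sequence] = []
        cin = 1
        for i in range(L):
            self.enc_blocks.append(
                _residual_group(cin, self.enc_widths[i], n_convs[i], k, p, rng, f"enc{i}")
            )
            nxt = self.enc_widths[i + 1] if i + 1 < L else bottom_width
            self.downs.append(
                Sequence(
                    [DownConv2x(self.enc_widths[i], nxt, rng, name=f"down{i}")]
                    + [
                        BatchNorm3d(nxt, name=f"down{i}.bn"),
                        PReLU(nxt, name=f"down{i}.prelu"),
                        SpatialDropout(p, rng),
                    ]
                )
            )
            cin = nxt
        self.bottom = _residual_group(bottom_width, bottom_width, 3, k, p, rng, "bottom")

        self.ups: list[Sequence] = []
        self.dec_blocks: list[ResidualBlock] = []
        cur = bottom_width
        for i in range(L - 1, -1, -1):
            wd = self.dec_widths[i]
            self.ups.append(
                Sequence(
                    [UpConv2x(cur, wd, rng, name=f"up{i}")]
                    + [
                        BatchNorm3d(wd, name=f"up{i}.bn"),
                        PReLU(wd, name=f"up{i}.prelu"),
                        SpatialDropout(p, rng),
                    ]
                )
            )
            cat = wd + self.enc_widths[i]
            self.dec_blocks.append(
                _residual_group(cat, wd, min(i + 1, 3), k, p, rng, f"dec{i}")
            )
            cur = wd
        self.out_conv = Conv3d(cur, 2, 1, rng, name="output")
        self._tape: dict | None = None

    # -- parameters ------------------------------------------------------------
    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for blk in self.enc_blocks:
            params += blk.params()
        for d in self.downs:
            params += d.params()
        params += self.bottom.params()
        for u in self.ups:
            params += u.params()
        for blk in self.dec_blocks:
            params += blk.params()
        params += self.out_conv.params()
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def parameter_summary(self) -> pd.DataFrame:
        """Per-weight-tensor audit table (name, shape, count)."""
        rows = [
            {"name": p.name, "shape": "x".join(map(str, p.value.shape)), "n": p.value.size}
            for p in self.parameters()
        ]
        return pd.DataFrame(rows)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # -- forward / backward ----------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Input (1, D, H, W) float32 -> softmax probabilities (2, D, H, W)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[0] != 1:
            raise ValueError(f"expected a (1, D, H, W) input, got shape {x.shape}")
        L = self.config.levels
        feats, pads = [], []
        for i in range(L):
            x = self.enc_blocks[i].forward(x, training)
            feats.append(x)
            pad = tuple((0, s % 2) for s in x.shape[1:])
            pads.append(pad)
            if any(p[1] for p in pad):
                x = np.pad(x, ((0, 0),) + pad)
            x = self.downs[i].forward(x, training)
        x = self.bottom.forward(x, training)
        for j, i in enumerate(range(L - 1, -1, -1)):
            x = self.ups[j].forward(x, training)
            fs = feats[i].shape
            x = x[:, : fs[1], : fs[2], : fs[3]]  # undo pre-down padding
            x = np.concatenate([feats[i], x], axis=0)
            x = self.dec_blocks[j].forward(x, training)
        z = self.out_conv.forward(x, training)
        p = softmax_channels(z)
        if training:
            self._tape = {"p": p, "pads": pads, "feat_channels": [f.shape[0] for f in feats],
                          "feat_shapes": [f.shape for f in feats]}
        return p

    def backward(self, dp: np.ndarray) -> None:
        """Backpropagate dL/d(probabilities); accumulates parameter grads."""
        if self._tape is None:
            raise RuntimeError("backward called without a training-mode forward")
        tape = self._tape
        L = self.config.levels
        dz = softmax_backward(tape["p"], dp)
        d = self.out_conv.backward(dz)
        dfeat: dict[int, np.ndarray] = {}
        for j, i in zip(range(L - 1, -1, -1), range(L)):
            dcat = self.dec_blocks[j].backward(d)
            c_feat = tape["feat_channels"][i]
            dfeat[i] = dcat[:c_feat]
            du = dcat[c_feat:]
            pad = tape["pads"][i]
            if any(p[1] for p in pad):
                du = np.pad(du, ((0, 0),) + pad)
            d = self.ups[j].backward(du)
        d = self.bottom.backward(d)
        for i in range(L - 1, -1, -1):
            d = self.downs[i].backward(d)
            fs = tape["feat_shapes"][i]
            d = d[:, : fs[1], : fs[2], : fs[3]]
            d = d + dfeat[i]
            d = self.enc_blocks[i].backward(d)
        self._tape = None

    # -- checkpointing ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name} in checkpoint")
            if state[p.name].shape != p.value.shape:
                raise ValueError(
                    f"shape mismatch for {p.name}: {state[p.name].shape} vs {p.value.shape}"
                )
            p.value[...] = state[p.name]

    def save_checkpoint(self, path: str | Path) -> None:
        np.savez_compressed(str(path), **self.state_dict())
        self.config.to_json(str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json")

    @classmethod
    def load_checkpoint(cls, path: str | Path, seed: int = 0) -> "ResidualUNet3D":
        cfg_path = str(path)[:-4] + ".json" if str(path).endswith(".npz") else str(path) + ".json"
        net = cls(NetworkConfig.from_json(cfg_path), seed=seed)
        with np.load(str(path)) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return net


def build_network(config: NetworkConfig, seed: int = 0) -> ResidualUNet3D:
    """Construct the parameterized segmentation network."""
    return ResidualUNet3D(config, seed=seed)


def predict(shell: PartialShell, network: ResidualUNet3D) -> LAGeometry:
    """Segment an LA volume from a partial shell: argmax over the 2 softmax
    channels, returned with the shell's spacing and crop metadata."""
    vol = shell.volume
    if vol.ndim != 3:
        raise ValueError(f"shell volume must be 3D, got shape {vol.shape}")
    p = network.forward(vol.astype(np.float32)[None], training=False)
    mask = p[1] > p[0]
    return LAGeometry(
        mask=mask,
        spacing_mm=shell.spacing_mm,
        pv_landmarks=None,
        origin=shell.crop_origin * shell.spacing_mm,
    )
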