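"""Forward-only ResNet-50 backbone with a self-attention feature head.

Assembles the standard 50-layer residual architecture — a 7x7 stride-2 stem,
3x3 stride-2 max pool, four stages of bottleneck blocks ([3, 4, 6, 3]) with
1x1 reduce/expand filters and identity skip connections, global average
pooling to 2,048 channels — and replaces the classifier with the attention
head, preserving the N x 2,048 extracted-feature contract.

The network is built for feature-shape and wiring verification, not
training: weights are He-initialized from a seeded RNG and normalization
layers standardize activations with batch statistics, so a forward pass is
deterministic for fixed (seed, input). Everything runs in float32 NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .attention import AttentionHeadConfig, attention_head

_STAGE_BLOCKS = (3, 4, 6, 3)
_STAGE_WIDTHS = (64, 128, 256, 512)
_EXPANSION = 4
DEFAULT_EXTRACTION_BATCH = 128


def _he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> np.ndarray:
    std = np.sqrt(2.0 / (c_in * k * k))
    return rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(np.float32)


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """x: (B, C, H, W); w: (O, C, k, k) -> (B, O, H', W') via im2col."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    k = w.shape[2]
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    out = cols @ w.reshape(w.shape[0], -1).T
    return out.reshape(b, ho, wo, w.shape[0]).transpose(0, 3, 1, 2)


def _batchnorm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    # untrained network: standardize with batch statistics per channel
    mean = x.mean(axis=(0, 2, 3), keepdims=True)
    var = x.var(axis=(0, 2, 3), keepdims=True)
    return (x - mean) / np.sqrt(var + eps)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    return win.max(axis=(4, 5))


@dataclass
class _Bottleneck:
    w_reduce: np.ndarray  # 1x1 channel reduction
    w_conv: np.ndarray  # 3x3 spatial filter
    w_expand: np.ndarray  # 1x1 channel expansion
    w_skip: np.ndarray | None  # 1x1 projection when shape changes
    stride: int

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = _relu(_batchnorm(_conv2d(x, self.w_reduce)))
        y = _relu(_batchnorm(_conv2d(y, self.w_conv, stride=self.stride, pad=1)))
        y = _batchnorm(_conv2d(y, self.w_expand))
        skip = x if self.w_skip is None else _batchnorm(_conv2d(x, self.w_skip, stride=self.stride))
        return _relu(y + skip)


class ResNetSelf:
    """Assembled backbone + attention head; call :meth:`forward` on a batch."""

    def __init__(self, cfg: AttentionHeadConfig | None = None, seed: int = 0):
        if cfg is None:
            cfg = AttentionHeadConfig(input_dim=2048, feature_dim=2048, seed=seed)
        if cfg.input_dim != _STAGE_WIDTHS[-1] * _EXPANSION:
            raise ValueError("head input_dim must equal the pooled width (2048)")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.w_stem = _he_conv(rng, 64, 3, 7)
        self.blocks: list[_Bottleneck] = []
        c_in = 64
        for stage, (n_blocks, width) in enumerate(zip(_STAGE_BLOCKS, _STAGE_WIDTHS)):
            for b in range(n_blocks):
                stride = 2 if (b == 0 and stage > 0) else 1
                c_out = width * _EXPANSION
                skip = None
                if stride != 1 or c_in != c_out:
                    skip = _he_conv(rng, c_out, c_in, 1)
                self.blocks.append(
                    _Bottleneck(
                        w_reduce=_he_conv(rng, width, c_in, 1),
                        w_conv=_he_conv(rng, width, width, 3),
                        w_expand=_he_conv(rng, c_out, width, 1),
                        w_skip=skip,
                        stride=stride,
                    )
                )
                c_in = c_out

    @property
    def feature_dim(self) -> int:
        return self.cfg.feature_dim

    def forward(self, images: np.ndarray) -> np.ndarray:
        """Images (B, H, W, 3) or (B, H, W) in [0, 1] -> features (B, feature_dim)."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:  # grayscale batch -> replicate channels
            x = np.repeat(x[..., None], 3, axis=-1)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError("expected a batch shaped (B, H, W, 3)")
        if min(x.shape[1], x.shape[2]) < 32:
            raise ValueError("images must be at least 32 x 32")
        x = x.transpose(0, 3, 1, 2)
        x = _relu(_batchnorm(_conv2d(x, self.w_stem, stride=2, pad=3)))
        x = _maxpool(x)
        for block in self.blocks:
            x = block.forward(x)
        pooled = x.mean(axis=(2, 3))  # global average pool -> (B, 2048)
        return np.stack([attention_head(row, self.cfg) for row in pooled])

    def extract(self, images: np.ndarray, batch_size: int = DEFAULT_EXTRACTION_BATCH) -> np.ndarray:
        """Batched feature extraction (default batch 128)."""
        if batch_size < 1:
            raise ValueError("batch_size must be positive")
        chunks = [
            self.forward(images[i : i + batch_size]) for i in range(0, len(images), batch_size)
        ]
        return np.concatenate(chunks, axis=0)


def build_resnet_self(cfg: AttentionHeadConfig | None = None, seed: int = 0) -> ResNetSelf:
    """Build the untrained backbone + head; see :class:`ResNetSelf`."""
    return ResNetSelf(cfg=cfg, seed=seed)
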