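"""The 3D-CNN block classifier.

Layer stack (channel-first shapes, input 4×16³):

    Conv3D(2, 8³) → Conv3D(4, 8³) → MaxPool(2³) → Dropout 0.25
    → Conv3D(8, 4³) → Conv3D(16, 4³) → MaxPool(2³)
    → Conv3D(32, 2³) → Conv3D(64, 2³) → Dropout 0.25
    → Flatten (64·4³ = 4096) → Dense 128 → Dropout 0.5 → Dense 1, sigmoid

All convolutions are ReLU with 'same' padding, so spatial dims go
16 → 16 → 8 → 8 → 4 → 4 and the flattened feature length entering the first
dense layer is 4096.  Loss, optimizer and schedule are configurable; the
defaults are binary cross-entropy with Adam at 1e−3, batch 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .descriptor import SampleBlock
from .nn import Conv3D, Dense, Dropout, Flatten, MaxPool3D, Network, ReLU

IN_CHANNELS = 4
IN_SIZE = 16
FLATTEN_LENGTH = 4096


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training hyper-parameters of the block classifier."""

    conv_filters: tuple[int, ...] = (2, 4, 8, 16, 32, 64)
    conv_kernels: tuple[int, ...] = (8, 8, 4, 4, 2, 2)
    dropout_rates: tuple[float, float, float] = (0.25, 0.25, 0.5)
    dense_width: int = 128
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 5
    patience: int = 1
    monitor: str = "val_accuracy"
    seed: int = 0

    def fingerprint(self) -> str:
        return (
            f"conv{self.conv_filters}-k{self.conv_kernels}"
            f"-drop{self.dropout_rates}-dense{self.dense_width}"
        )


def build_model(config: NetworkConfig | None = None) -> Network:
    """Instantiate the (untrained) classifier; validates the layer shapes."""
    cfg = config or NetworkConfig()
    if len(cfg.conv_filters) != 6 or len(cfg.conv_kernels) != 6:
        raise ValueError("the classifier has exactly 6 convolution layers")
    rng = np.random.default_rng(cfg.seed)
    f, k, d = cfg.conv_filters, cfg.conv_kernels, cfg.dropout_rates
    layers = [
        Conv3D(IN_CHANNELS, f[0], k[0], rng), ReLU(),
        Conv3D(f[0], f[1], k[1], rng), ReLU(),
        MaxPool3D(),
        Dropout(d[0]),
        Conv3D(f[1], f[2], k[2], rng), ReLU(),
        Conv3D(f[2], f[3], k[3], rng), ReLU(),
        MaxPool3D(),
        Conv3D(f[3], f[4], k[4], rng), ReLU(),
        Conv3D(f[4], f[5], k[5], rng), ReLU(),
        Dropout(d[1]),
        Flatten(),
    ]
    flat = f[5] * (IN_SIZE // 4) ** 3
    model = Network(layers, seed=cfg.seed, fingerprint=cfg.fingerprint())
    traced_flat = model.shape_trace((IN_CHANNELS, IN_SIZE, IN_SIZE, IN_SIZE))[-1][0]
    if traced_flat != flat:
        raise ValueError(f"flattened length {traced_flat} != expected {flat}")
    layers += [
        Dense(flat, cfg.dense_width, rng), ReLU(),
        Dropout(d[2]),
        Dense(cfg.dense_width, 1, rng),
    ]
    return model


def blocks_to_arrays(blocks: list[SampleBlock]) -> tuple[np.ndarray, np.ndarray]:
    """Stack blocks into (N, 4, 16, 16, 16) float32 inputs and a label vector."""
    if not blocks:
        return (
            np.empty((0, IN_CHANNELS, IN_SIZE, IN_SIZE, IN_SIZE), dtype=np.float32),
            np.empty((0,)),
        )
    x = np.stack([b.values for b in blocks]).transpose(0, 4, 1, 2, 3).astype(np.float32)
    y = np.array([0.0 if b.label is None else float(b.label) for b in blocks])
    return x, y


def train_model(
    model: Network,
    train_set: tuple[np.ndarray, np.ndarray] | list[SampleBlock],
    val_set: tuple[np.ndarray, np.ndarray] | list[SampleBlock] | None = None,
    config: NetworkConfig | None = None,
    **fit_kwargs,
) -> Network:
    """Train on labeled normalized blocks; returns the model with history."""
    cfg = config or NetworkConfig()
    if isinstance(train_set, list):
        train_set = blocks_to_arrays(train_set)
    if isinstance(val_set, list):
        val_set = blocks_to_arrays(val_set)
    x, y = train_set
    if len(x) == 0:
        raise ValueError("empty training set")
    return model.fit(
        x,
        y,
        validation=val_set,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        patience=cfg.patience,
        monitor=cfg.monitor,
        **fit_kwargs,
    )


def predict_blocks(model: Network, blocks: list[SampleBlock]) -> np.ndarray:
    """One probability per block, order preserved."""
    if not blocks:
        return np.empty(0)
    x, _ = blocks_to_arrays(blocks)
    if x.shape[1:] != (IN_CHANNELS, IN_SIZE, IN_SIZE, IN_SIZE):
        raise ValueError("blocks must be 16^3 x 4")
    return model.predict_proba(x)
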