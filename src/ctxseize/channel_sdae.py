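"""Per-channel stacked denoising autoencoders and the EEG-word dictionary.

One 2-layer SDAE is trained per EEG channel on that channel's scalogram
vectors (default hidden sizes 80 then 60).  Each denoising autoencoder maps
a masked copy of its input through a sigmoid encoder and sigmoid decoder
and is trained to minimize the cross-entropy reconstruction error of the
*clean* input, by mini-batch SGD.  Stacking is greedy and layer-wise: layer
1 trains on the raw vectors; its clean hidden codes (no corruption) become
layer 2's training data, with layer 1 frozen.

The last hidden layer doubles as a dictionary of basic scalogram patterns:
a fragment is translated to the "EEG word" indexed by its maximally
activated last-layer unit (ties break to the lowest index), and the
concatenated last-layer activations over channels form the channel-wise
feature block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_EPS = 1e-12


@dataclass
class DAELayer:
    """Untied encoder/decoder weights of one denoising autoencoder."""

    W_enc: np.ndarray  # (hidden, visible)
    b_enc: np.ndarray  # (hidden,)
    W_dec: np.ndarray  # (visible, hidden)
    b_dec: np.ndarray  # (visible,)

    @property
    def n_visible(self) -> int:
        return self.W_enc.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_enc.shape[0]


@dataclass
class CorruptionConfig:
    """Masking noise: each coordinate is zeroed independently with ``fraction``."""

    kind: str = "masking"
    fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "masking":
            raise ValueError(f"unsupported corruption kind {self.kind!r}")
        if not 0 <= self.fraction <= 1:
            raise ValueError("corruption fraction must lie in [0, 1]")


@dataclass
class TrainConfig:
    epochs: int = 40
    batch_size: int = 16
    learning_rate: float = 0.5
    l2_penalty: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0 or self.l2_penalty < 0:
            raise ValueError("learning_rate must be > 0 and l2_penalty >= 0")


@dataclass(frozen=True)
class EEGWord:
    """Index of the dictionary pattern (hidden unit) a fragment activates most."""

    word_id: int
    channel_id: int


@dataclass
class SDAEModel:
    layers: list[DAELayer]
    channel_id: int = 0
    # one entry per layer: {"init": loss, "final": loss, "epochs": [...]}
    # losses are clean-input reconstruction cross-entropies on the layer's
    # own training data, before the first and after the last update
    training_log: list[dict] = field(default_factory=list)

    @property
    def dictionary_size(self) -> int:
        """Vocabulary size of this channel = last hidden layer width."""
        return self.layers[-1].n_hidden


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    if z.ndim == 0:  # scalar path (hierarchical-softmax branches)
        if z >= 0:
            return np.float64(1.0 / (1.0 + np.exp(-z)))
        ez = np.exp(z)
        return np.float64(ez / (1.0 + ez))
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def corrupt(x: np.ndarray, cfg: CorruptionConfig) -> np.ndarray:
    """Return a masked copy of x with each entry zeroed w.p. ``cfg.fraction``."""
    rng = np.random.default_rng(cfg.seed)
    return _corrupt(np.asarray(x, dtype=np.float64), cfg.fraction, rng)


def _corrupt(x: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    if fraction == 0:
        return x.copy()
    keep = rng.random(x.shape) >= fraction
    return x * keep


def dae_forward(layer: DAELayer, x_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid encoder then sigmoid decoder: h = f(W x̂ + b), y = f(W' h + b')."""
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x_hat.shape[-1] != layer.n_visible:
        raise ValueError(
            f"input dimension {x_hat.shape[-1]} != visible size {layer.n_visible}"
        )
    h = sigmoid(x_hat @ layer.W_enc.T + layer.b_enc)
    y = sigmoid(h @ layer.W_dec.T + layer.b_dec)
    return h, y


def dae_loss(x: np.ndarray, y: np.ndarray) -> float:
    """Cross-entropy reconstruction error, summed over units (mean over a batch).

    Reconstructions exactly at 0 or 1 are clamped by 1e-12.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.clip(np.asarray(y, dtype=np.float64), _EPS, 1 - _EPS)
    ce = -(x * np.log(y) + (1 - x) * np.log(1 - y))
    if x.ndim == 1:
        return float(ce.sum())
    return float(ce.sum(axis=1).mean())


def _init_layer(n_visible: int, n_hidden: int, rng: np.random.Generator) -> DAELayer:
    # Glorot-uniform for sigmoid units
    def glorot(n_out, n_in):
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_out, n_in))

    return DAELayer(
        W_enc=glorot(n_hidden, n_visible),
        b_enc=np.zeros(n_hidden),
        W_dec=glorot(n_visible, n_hidden),
        b_dec=np.zeros(n_visible),
    )


def _train_single_dae(
    data: np.ndarray,
    n_hidden: int,
    fraction: float,
    tc: TrainConfig,
    rng: np.random.Generator,
) -> tuple[DAELayer, dict]:
    n, n_visible = data.shape
    layer = _init_layer(n_visible, n_hidden, rng)
    lr = tc.learning_rate
    log: list[float] = []
    init_loss = dae_loss(data, dae_forward(layer, data)[1])
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, tc.batch_size):
            batch = data[order[lo : lo + tc.batch_size]]
            b = batch.shape[0]
            x_hat = _corrupt(batch, fraction, rng)
            h, y = dae_forward(layer, x_hat)
            loss = dae_loss(batch, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite DAE loss at epoch {epoch}, batch offset {lo}: "
                    f"{loss}; reduce the learning rate"
                )
            epoch_loss += loss * b
            delta_y = (np.clip(y, _EPS, 1 - _EPS) - batch) / b
            delta_h = (delta_y @ layer.W_dec) * h * (1 - h)
            layer.W_dec -= lr * (delta_y.T @ h + tc.l2_penalty * layer.W_dec)
            layer.b_dec -= lr * delta_y.sum(axis=0)
            layer.W_enc -= lr * (delta_h.T @ x_hat + tc.l2_penalty * layer.W_enc)
            layer.b_enc -= lr * delta_h.sum(axis=0)
        log.append(epoch_loss / n)
    final_loss = dae_loss(data, dae_forward(layer, data)[1])
    return layer, {"init": init_loss, "final": final_loss, "epochs": log}


def train_sdae(
    data: np.ndarray | Sequence,
    sizes: Sequence[int] = (80, 60),
    corr: CorruptionConfig | None = None,
    tc: TrainConfig | None = None,
    channel_id: int = 0,
) -> SDAEModel:
    """Greedy layer-wise training of the stacked denoising autoencoders.

    ``data`` holds one channel's scalogram vectors, one row per fragment
    (ScalogramVector objects are accepted).  Each layer trains as a DAE on
    the clean hidden codes of the already-frozen layers beneath it;
    corruption applies only to the layer currently training.  Fully seeded.
    """
    corr = corr or CorruptionConfig()
    tc = tc or TrainConfig()
    rows = [getattr(v, "values", v) for v in data]
    X = np.asarray(rows, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("training data must be a collection of equal-length vectors")
    if X.shape[0] < tc.batch_size:
        raise ValueError(
            f"need at least batch_size={tc.batch_size} samples, got {X.shape[0]}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, corr.seed, channel_id]))
    layers: list[DAELayer] = []
    logs: list[dict] = []
    current = X
    for n_hidden in sizes:
        layer, log = _train_single_dae(current, n_hidden, corr.fraction, tc, rng)
        layers.append(layer)
        logs.append(log)
        current = sigmoid(current @ layer.W_enc.T + layer.b_enc)  # clean codes
    return SDAEModel(layers, channel_id=channel_id, training_log=logs)


def encode(model: SDAEModel, v: np.ndarray) -> np.ndarray:
    """Last-hidden-layer activations of clean (uncorrupted) input."""
    h = np.asarray(getattr(v, "values", v), dtype=np.float64)
    for layer in model.layers:
        h = sigmoid(h @ layer.W_enc.T + layer.b_enc)
    return h


def encode_channelwise(
    models: Sequence[SDAEModel], frag_vectors: Sequence[np.ndarray]
) -> np.ndarray:
    """Concatenate last-layer codes across channels (the channel-wise feature)."""
    if len(models) != len(frag_vectors):
        raise ValueError(
            f"{len(models)} models but {len(frag_vectors)} channel vectors"
        )
    return np.concatenate([encode(m, v) for m, v in zip(models, frag_vectors)])


def translate_to_word(model: SDAEModel, v: np.ndarray) -> EEGWord:
    """Max-probability pooling: the word is the argmax last-layer unit.

    Ties break to the lowest unit index (np.argmax convention).
    """
    code = encode(model, v)
    return EEGWord(word_id=int(np.argmax(code)), channel_id=model.channel_id)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_sdae(model: SDAEModel, path: str | Path) -> None:
    arrays = {"channel_id": np.array(model.channel_id),
              "n_layers": np.array(len(model.layers))}
    for i, layer in enumerate(model.layers):
        arrays[f"W_enc_{i}"] = layer.W_enc
        arrays[f"b_enc_{i}"] = layer.b_enc
        arrays[f"W_dec_{i}"] = layer.W_dec
        arrays[f"b_dec_{i}"] = layer.b_dec
    np.savez_compressed(path, **arrays)


def load_sdae(path: str | Path) -> SDAEModel:
    with np.load(path) as npz:
        layers = [
            DAELayer(
                W_enc=npz[f"W_enc_{i}"], b_enc=npz[f"b_enc_{i}"],
                W_dec=npz[f"W_dec_{i}"], b_dec=npz[f"b_dec_{i}"],
            )
            for i in range(int(npz["n_layers"]))
        ]
        return SDAEModel(layers, channel_id=int(npz["channel_id"]))
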