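"""Classifiers for S2I-transformed images.

Two interchangeable architectures behind one train/predict contract:

* **transformer** — the image is cut into non-overlapping patches (8x8 by
  default), each linearly embedded to ``hidden_size`` with a learned
  positional embedding; a stack of encoder layers (multi-head scaled
  dot-product self-attention, Add&Norm, feed-forward) processes the patch
  tokens, and a decoder stack driven by a single learned class-query token
  cross-attends to the encoder memory; a final linear + softmax yields class
  probabilities. Defaults follow the reference configuration: 3 encoder and
  3 decoder layers, hidden size 32, 2 heads, dropout 0.5, Adam with lr 1e-3
  decayed by 0.97 per epoch, batch size 256.
* **cnn** — the ablation network: four 3x3 convolution blocks
  (16/32/64/64 channels, ReLU, 2x2 max-pool) then linear + softmax.

Also here: the hand-crafted statistical feature extractor used by classical
baselines (length, mean, std, min, max, median, skewness, kurtosis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats as _sps

from ._autograd import Adam, Tensor
from .signal_io import ImageDataset, RawRecord

__all__ = [
    "ModelConfig",
    "FeatureVector",
    "TrainedModel",
    "scaled_dot_product_attention",
    "build_model",
    "train",
    "predict",
    "extract_features",
]


@dataclass
class ModelConfig:
    """Architecture and training schedule hyperparameters."""

    arch: str = "transformer"  # "transformer" | "cnn"
    n_encoder_layers: int = 3
    n_decoder_layers: int = 3
    hidden_size: int = 32
    n_heads: int = 2
    dropout: float = 0.5
    patch_size: int = 8
    n_classes: int = 2
    lr: float = 1e-3
    lr_decay: float = 0.97  # multiplicative, per epoch
    batch_size: int = 256
    epochs: int = 20
    seed: int = 0
    ffn_mult: int = 4  # feed-forward width = ffn_mult * hidden_size

    def __post_init__(self) -> None:
        if self.arch not in ("transformer", "cnn"):
            raise ValueError(f"arch must be 'transformer' or 'cnn', got {self.arch!r}")
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass(frozen=True)
class FeatureVector:
    """Summary statistics of one raw signal (classical-baseline features)."""

    length: int
    mean: float
    std: float
    min: float
    max: float
    median: float
    skewness: float
    kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array([self.length, self.mean, self.std, self.min,
                         self.max, self.median, self.skewness, self.kurtosis])


def scaled_dot_product_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """``softmax(Q K^T / sqrt(d_k)) V`` — the core attention operator.

    ``Q`` and ``K`` must share their column count ``d_k``; ``K`` and ``V``
    must share their row count. Rows of the output are convex combinations of
    the rows of ``V``.
    """
    Q, K, V = (np.asarray(m, dtype=float) for m in (Q, K, V))
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"Q and K must share d_k: {Q.shape[-1]} != {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise ValueError(f"K and V must share row count: {K.shape[-2]} != {V.shape[-2]}")
    d_k = Q.shape[-1]
    logits = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    logits -= logits.max(axis=-1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ V


def extract_features(rec: RawRecord) -> FeatureVector:
    """Statistical feature vector of a raw signal.

    Population std (divisor n); skewness and excess kurtosis as standardized
    central moments, defined as 0 for a constant signal.
    """
    s = rec.signal
    std = float(s.std())
    if std == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(_sps.skew(s, bias=True))
        kurt = float(_sps.kurtosis(s, fisher=True, bias=True))
    return FeatureVector(
        length=int(s.size),
        mean=float(s.mean()),
        std=std,
        min=float(s.min()),
        max=float(s.max()),
        median=float(np.median(s)),
        skewness=skew,
        kurtosis=kurt,
    )


# --------------------------------------------------------------------------
# networks


def _linear_params(rng: np.random.Generator, fan_in: int, fan_out: int) -> tuple[Tensor, Tensor]:
    w = Tensor(rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), (fan_in, fan_out)),
               requires_grad=True)
    b = Tensor(np.zeros(fan_out), requires_grad=True)
    return w, b


class _AttentionBlock:
    """Multi-head attention with output projection."""

    def __init__(self, rng: np.random.Generator, d: int, heads: int) -> None:
        self.d, self.h = d, heads
        self.wq, self.bq = _linear_params(rng, d, d)
        self.wk, self.bk = _linear_params(rng, d, d)
        self.wv, self.bv = _linear_params(rng, d, d)
        self.wo, self.bo = _linear_params(rng, d, d)

    def params(self) -> list[Tensor]:
        return [self.wq, self.bq, self.wk, self.bk, self.wv, self.bv, self.wo, self.bo]

    def __call__(self, xq: Tensor, xkv: Tensor) -> Tensor:
        B, Nq, d = xq.shape
        Nk = xkv.shape[1]
        h, dk = self.h, d // self.h

        def heads(x: Tensor, w: Tensor, b: Tensor, N: int) -> Tensor:
            y = x @ w + b  # (B, N, d)
            return y.reshape(B, N, h, dk).transpose(0, 2, 1, 3)  # (B, h, N, dk)

        q = heads(xq, self.wq, self.bq, Nq)
        k = heads(xkv, self.wk, self.bk, Nk)
        v = heads(xkv, self.wv, self.bv, Nk)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
        z = logits.softmax() @ v  # (B, h, Nq, dk)
        z = z.transpose(0, 2, 1, 3).reshape(B, Nq, d)
        return z @ self.wo + self.bo


class _FFN:
    def __init__(self, rng: np.random.Generator, d: int, mult: int) -> None:
        self.w1, self.b1 = _linear_params(rng, d, mult * d)
        self.w2, self.b2 = _linear_params(rng, mult * d, d)

    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        return ((x @ self.w1 + self.b1).relu()) @ self.w2 + self.b2


class _Norm:
    def __init__(self, d: int) -> None:
        self.g = Tensor(np.ones(d), requires_grad=True)
        self.b = Tensor(np.zeros(d), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.g, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.g, self.b)


class TransformerNet:
    """Patch-token encoder + class-query decoder classifier."""

    def __init__(self, config: ModelConfig, image_size: int) -> None:
        if image_size % config.patch_size != 0:
            raise ValueError(
                f"image_size {image_size} not divisible by patch_size {config.patch_size}"
            )
        self.config = config
        self.image_size = image_size
        p = config.patch_size
        self.n_tokens = (image_size // p) ** 2
        d = config.hidden_size
        rng = np.random.default_rng(config.seed)
        self.embed_w, self.embed_b = _linear_params(rng, p * p, d)
        self.pos = Tensor(rng.normal(0.0, 0.02, (self.n_tokens, d)), requires_grad=True)
        self.query = Tensor(rng.normal(0.0, 0.02, (1, 1, d)), requires_grad=True)
        self.enc = []
        for _ in range(config.n_encoder_layers):
            self.enc.append({
                "attn": _AttentionBlock(rng, d, config.n_heads), "n1": _Norm(d),
                "ffn": _FFN(rng, d, config.ffn_mult), "n2": _Norm(d),
            })
        self.dec = []
        for _ in range(config.n_decoder_layers):
            self.dec.append({
                "self": _AttentionBlock(rng, d, config.n_heads), "n1": _Norm(d),
                "cross": _AttentionBlock(rng, d, config.n_heads), "n2": _Norm(d),
                "ffn": _FFN(rng, d, config.ffn_mult), "n3": _Norm(d),
            })
        self.head_w, self.head_b = _linear_params(rng, d, config.n_classes)

    def params(self) -> list[Tensor]:
        ps = [self.embed_w, self.embed_b, self.pos, self.query, self.head_w, self.head_b]
        for layer in self.enc + self.dec:
            for block in layer.values():
                ps.extend(block.params())
        return ps

    def _patchify(self, images: np.ndarray) -> np.ndarray:
        B = images.shape[0]
        p = self.config.patch_size
        g = self.image_size // p
        x = images.reshape(B, g, p, g, p).transpose(0, 1, 3, 2, 4)
        return x.reshape(B, g * g, p * p)

    def forward(self, images: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        cfg = self.config
        drop = cfg.dropout
        rng = rng or np.random.default_rng(0)
        x = Tensor(self._patchify(images))
        h = (x @ self.embed_w + self.embed_b) + self.pos
        for layer in self.enc:
            a = layer["attn"](h, h).dropout(drop, rng, train)
            h = layer["n1"](h + a)
            f = layer["ffn"](h).dropout(drop, rng, train)
            h = layer["n2"](h + f)
        memory = h
        B = images.shape[0]
        q = self.query + Tensor(np.zeros((B, 1, cfg.hidden_size)))
        for layer in self.dec:
            a = layer["self"](q, q).dropout(drop, rng, train)
            q = layer["n1"](q + a)
            c = layer["cross"](q, memory).dropout(drop, rng, train)
            q = layer["n2"](q + c)
            f = layer["ffn"](q).dropout(drop, rng, train)
            q = layer["n3"](q + f)
        return q.reshape(B, cfg.hidden_size) @ self.head_w + self.head_b


class ConvNet:
    """Four 3x3 conv blocks (ReLU + 2x2 max-pool) then linear + softmax."""

    CHANNELS = (16, 32, 64, 64)

    def __init__(self, config: ModelConfig, image_size: int) -> None:
        if image_size % 16 != 0:
            raise ValueError("cnn requires image_size divisible by 16 (four 2x2 pools)")
        self.config = config
        self.image_size = image_size
        rng = np.random.default_rng(config.seed)
        self.convs = []
        c_in = 1
        for c_out in self.CHANNELS:
            fan = c_in * 9
            w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan), (c_out, c_in, 3, 3)), requires_grad=True)
            b = Tensor(np.zeros(c_out), requires_grad=True)
            self.convs.append((w, b))
            c_in = c_out
        feat = self.CHANNELS[-1] * (image_size // 16) ** 2
        self.head_w, self.head_b = _linear_params(rng, feat, config.n_classes)

    def params(self) -> list[Tensor]:
        ps = []
        for w, b in self.convs:
            ps.extend([w, b])
        ps.extend([self.head_w, self.head_b])
        return ps

    def forward(self, images: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        B = images.shape[0]
        h = Tensor(images.reshape(B, 1, self.image_size, self.image_size))
        for w, b in self.convs:
            h = h.conv2d(w, b, pad=1).relu().maxpool2d(2)
        h = h.reshape(B, -1)
        return h @ self.head_w + self.head_b


@dataclass
class TrainedModel:
    """A (possibly untrained) classifier plus its provenance."""

    config: ModelConfig
    net: object
    class_names: list[str]
    training_log: list[dict] = field(default_factory=list)

    def save(self, path: str) -> None:
        """Single-file checkpoint: weights plus embedded config and classes."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.net.params())}
        meta = json.dumps({
            "config": asdict(self.config),
            "class_names": self.class_names,
            "image_size": self.net.image_size,
            "training_log": self.training_log,
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = ModelConfig(**meta["config"])
            model = build_model(cfg, meta["image_size"], meta["class_names"])
            for i, p in enumerate(model.net.params()):
                p.data[...] = z[f"p{i}"]
        model.training_log = meta["training_log"]
        return model


def build_model(config: ModelConfig, image_size: int,
                class_names: Optional[list[str]] = None) -> TrainedModel:
    """Construct an untrained model; parameter init is deterministic in
    ``config.seed``."""
    names = list(class_names) if class_names else [str(i) for i in range(config.n_classes)]
    if len(names) != config.n_classes:
        raise ValueError("class_names length must equal n_classes")
    net = TransformerNet(config, image_size) if config.arch == "transformer" \
        else ConvNet(config, image_size)
    return TrainedModel(config=config, net=net, class_names=names)


def _forward_probs(net, images: np.ndarray, batch: int = 512) -> np.ndarray:
    out = []
    for s in range(0, len(images), batch):
        logits = net.forward(images[s : s + batch], train=False).data
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        out.append(e / e.sum(axis=-1, keepdims=True))
    return np.concatenate(out) if out else np.zeros((0, net.config.n_classes))


def train(model: TrainedModel, train_ds: ImageDataset, val_ds: ImageDataset,
          config: ModelConfig | None = None) -> TrainedModel:
    """Train with Adam and a per-epoch multiplicative lr decay.

    Logs per-epoch learning rate, mean train loss and validation accuracy;
    returns the model restored to its best-validation-accuracy parameters
    (ties resolved toward the later epoch). ``epochs == 0`` returns the
    initialized model with an empty log.
    """
    cfg = config or model.config
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation datasets must be nonempty")
    for ds in (train_ds, val_ds):
        if ds.labels.size and ds.labels.max() >= cfg.n_classes:
            raise ValueError("label outside the model's class range")
        if ds.image_size != model.net.image_size:
            raise ValueError("image size mismatch between dataset and model")
    net = model.net
    params = net.params()
    opt = Adam(params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    best_acc, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        lr = cfg.lr * cfg.lr_decay**epoch
        opt.lr = lr
        order = rng.permutation(len(train_ds))
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            opt.zero_grad()
            logits = net.forward(train_ds.images[idx], train=True, rng=rng)
            loss = logits.cross_entropy(train_ds.labels[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        probs = _forward_probs(net, val_ds.images)
        val_acc = float((probs.argmax(axis=1) == val_ds.labels).mean())
        model.training_log.append(
            {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc}
        )
        if val_acc >= best_acc:  # >= keeps the later epoch on ties
            best_acc = val_acc
            best_state = [p.data.copy() for p in params]
    if best_state is not None:
        for p, saved in zip(params, best_state):
            p.data[...] = saved
    return model


def predict(model: TrainedModel, images: ImageDataset | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (eval mode, dropout off; ties
    break toward the lowest class index via argmax)."""
    arr = images.images if isinstance(images, ImageDataset) else np.asarray(images, dtype=float)
    if len(arr) == 0:
        return np.zeros((0, model.config.n_classes)), np.zeros(0, dtype=int)
    if arr.shape[1] != model.net.image_size:
        raise ValueError(f"image size {arr.shape[1]} does not match model {model.net.image_size}")
    probs = _forward_probs(model.net, arr)
    return probs, probs.argmax(axis=1)
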