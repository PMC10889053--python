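"""Transformer over topological sequences: pretraining, regression, attribution.

Each filtration step carries a 143 x 6 feature matrix that a per-step
projection (a channel-mixing map equivalent to a 1x1 convolution followed
by a linear layer) flattens into a d_model vector; a trainable multiscale
(per-position) embedding is added before the encoder. Self-supervised
pretraining masks a random fraction of positions with a learned mask token
and trains an asymmetric encoder-decoder (decoder no deeper than the
encoder) to reconstruct the full input sequence under an MSE loss.
Fine-tuning attaches a scalar regression head to the encoder output at the
first sequence position. Attention uses the scaled dot product
softmax(Q K^T / sqrt(d_k)) V with d_k the per-head width.

Two attribution views are provided: the attention score (mean attention
weight onto each key position over all layers, heads and queries, a
length-T convex vector) and the saliency map (absolute input gradient of
the scalar prediction, same shape as the input).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor, parameter


class TrainingError(RuntimeError):
    """Raised when a training run diverges (NaN loss)."""


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    ``d_model`` must be divisible by ``n_heads``; the decoder is never
    deeper than the encoder (asymmetric reconstruction design).
    """

    seq_len: int = 50
    n_combos: int = 143
    n_statistics: int = 6
    d_model: int = 512
    n_heads: int = 8
    n_encoder_layers: int = 6
    n_decoder_layers: int = 2
    d_hidden: int | None = None       # per-step projection width
    d_ff: int | None = None           # feed-forward width
    learning_rate: float = 1e-3
    mask_ratio: float = 0.5
    loss: str = "mse"                 # "mse" or "mae"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.n_decoder_layers > self.n_encoder_layers:
            raise ValueError("decoder must not be deeper than the encoder")
        if not 0.0 <= self.mask_ratio < 1.0:
            raise ValueError("mask_ratio must be in [0, 1)")
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        if self.d_hidden is None:
            self.d_hidden = max(self.d_model // 2, 8)
        if self.d_ff is None:
            self.d_ff = 2 * self.d_model

    @property
    def n_features(self) -> int:
        return self.n_combos * self.n_statistics


def tiny_config(**overrides) -> ModelConfig:
    """A desk-scale configuration used throughout the test suite."""
    defaults = dict(d_model=32, n_heads=2, n_encoder_layers=2,
                    n_decoder_layers=1, d_hidden=16, d_ff=64)
    defaults.update(overrides)
    return ModelConfig(**defaults)


def paper_config(**overrides) -> ModelConfig:
    """The full-scale configuration (d_model = 512, asymmetric stack)."""
    defaults = dict(d_model=512, n_heads=8, n_encoder_layers=6, n_decoder_layers=2)
    defaults.update(overrides)
    return ModelConfig(**defaults)


class Linear:
    def __init__(self, rng, d_in: int, d_out: int) -> None:
        self.w = parameter(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class LayerNorm:
    def __init__(self, d: int) -> None:
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.bias = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.standardize(axis=-1) * self.gain + self.bias

    def params(self) -> list[Tensor]:
        return [self.gain, self.bias]


def attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention softmax(Q K^T / sqrt(d_k)) V.

    Returns (output, attention weights); weight rows sum to 1.
    """
    d_k = q.shape[-1]
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (1.0 / np.sqrt(d_k))
    weights = scores.softmax(axis=-1)
    return weights @ v, weights


class MultiHeadAttention:
    def __init__(self, rng, d_model: int, n_heads: int) -> None:
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)
        self.last_weights: np.ndarray | None = None  # (B, heads, T, T)

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        out, weights = attention(q, k, v)
        self.last_weights = weights.data.copy()
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(out)

    def params(self) -> list[Tensor]:
        return self.wq.params() + self.wk.params() + self.wv.params() + self.wo.params()


class TransformerLayer:
    """Post-norm block: self-attention and feed-forward, each with residual."""

    def __init__(self, rng, d_model: int, n_heads: int, d_ff: int) -> None:
        self.attn = MultiHeadAttention(rng, d_model, n_heads)
        self.norm1 = LayerNorm(d_model)
        self.ff1 = Linear(rng, d_model, d_ff)
        self.ff2 = Linear(rng, d_ff, d_model)
        self.norm2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x))
        x = self.norm2(x + self.ff2(self.ff1(x).relu()))
        return x

    def params(self) -> list[Tensor]:
        return (self.attn.params() + self.norm1.params() + self.ff1.params()
                + self.ff2.params() + self.norm2.params())


class TopologicalSequenceModel:
    """Encoder-decoder transformer over (T, 143, 6) topological sequences."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.proj1 = Linear(rng, c.n_features, c.d_hidden)
        self.proj2 = Linear(rng, c.d_hidden, c.d_model)
        self.positional = parameter(rng, c.seq_len, c.d_model, scale=0.02)
        self.mask_token = parameter(rng, c.d_model, scale=0.02)
        self.encoder = [TransformerLayer(rng, c.d_model, c.n_heads, c.d_ff)
                        for _ in range(c.n_encoder_layers)]
        self.decoder = [TransformerLayer(rng, c.d_model, c.n_heads, c.d_ff)
                        for _ in range(c.n_decoder_layers)]
        self.recon_head = Linear(rng, c.d_model, c.n_features)
        self.reg_head = Linear(rng, c.d_model, 1)
        self._rng = np.random.default_rng(c.seed + 1)

    # -- parameters -------------------------------------------------------

    def params(self) -> list[Tensor]:
        ps = (self.proj1.params() + self.proj2.params()
              + [self.positional, self.mask_token])
        for layer in self.encoder + self.decoder:
            ps += layer.params()
        return ps + self.recon_head.params() + self.reg_head.params()

    # -- forward passes ---------------------------------------------------

    @staticmethod
    def _as_batch(x: np.ndarray | Tensor, n_features: int) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=float))
        if x.ndim == 4:
            b, t = x.shape[:2]
            x = x.reshape(b, t, n_features)
        elif x.ndim == 3 and x.shape[-1] != n_features:
            x = x.reshape(1, x.shape[0], n_features)
        elif x.ndim == 2:
            x = x.reshape(1, *x.shape)
        return x

    def project_step(self, step_features: np.ndarray) -> np.ndarray:
        """Deterministic per-step projection of a 143 x 6 matrix to d_model."""
        flat = Tensor(np.asarray(step_features, dtype=float).reshape(1, -1))
        out = self.proj2(self.proj1(flat).relu())
        return out.data[0]

    def encode(self, x, mask: np.ndarray | None = None) -> Tensor:
        x = self._as_batch(x, self.config.n_features)
        h = self.proj2(self.proj1(x).relu())
        if mask is not None:
            m = Tensor(mask[..., None].astype(float))
            h = h * (1.0 - m) + self.mask_token * m
        h = h + self.positional
        for layer in self.encoder:
            h = layer(h)
        return h

    def reconstruct(self, x, mask: np.ndarray | None = None) -> Tensor:
        h = self.encode(x, mask=mask)
        for layer in self.decoder:
            h = layer(h)
        return self.recon_head(h)

    def forward_predict(self, x) -> Tensor:
        h = self.encode(x)
        first = h[:, 0, :]  # the foremost embedded vector is the latent feature
        return self.reg_head(first).reshape(-1)

    def predict(self, x) -> np.ndarray:
        return self.forward_predict(x).data

    # -- losses and training ----------------------------------------------

    def _loss(self, pred: Tensor, target: np.ndarray) -> Tensor:
        diff = pred - Tensor(target)
        if self.config.loss == "mse":
            return (diff * diff).mean()
        return diff.abs().mean()

    def reconstruction_loss(self, x: np.ndarray, mask: np.ndarray | None = None) -> float:
        x = np.asarray(x, dtype=float)
        flat = x.reshape(x.shape[0], self.config.seq_len, self.config.n_features)
        out = self.reconstruct(flat, mask=mask)
        return float(self._loss(out, flat).data)

    def _sample_mask(self, batch: int) -> np.ndarray | None:
        ratio = self.config.mask_ratio
        if ratio == 0.0:
            return None
        t = self.config.seq_len
        n_mask = max(1, int(round(ratio * t)))
        mask = np.zeros((batch, t), dtype=bool)
        for i in range(batch):
            mask[i, self._rng.choice(t, size=n_mask, replace=False)] = True
        return mask

    def pretrain(self, sequences: np.ndarray, steps: int = 300,
                 batch_size: int = 8) -> list[float]:
        """Masked-reconstruction pretraining; returns the per-step losses."""
        x = np.asarray(sequences, dtype=float)
        x = x.reshape(x.shape[0], self.config.seq_len, self.config.n_features)
        opt = Adam(self.params(), lr=self.config.learning_rate)
        losses: list[float] = []
        for step in range(steps):
            idx = self._rng.choice(len(x), size=min(batch_size, len(x)), replace=False)
            batch = x[idx]
            mask = self._sample_mask(len(batch))
            out = self.reconstruct(batch, mask=mask)
            loss = self._loss(out, batch)
            if not np.isfinite(loss.data):
                raise TrainingError(f"pretraining diverged at step {step}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        return losses

    def finetune(self, sequences: np.ndarray, labels: np.ndarray,
                 steps: int = 200, batch_size: int = 8) -> list[float]:
        """Supervised regression fine-tuning; returns the per-step losses."""
        x = np.asarray(sequences, dtype=float)
        x = x.reshape(x.shape[0], self.config.seq_len, self.config.n_features)
        y = np.asarray(labels, dtype=float).reshape(-1)
        if len(y) != len(x):
            raise ValueError("labels must match the number of sequences")
        opt = Adam(self.params(), lr=self.config.learning_rate)
        losses: list[float] = []
        for step in range(steps):
            idx = self._rng.choice(len(x), size=min(batch_size, len(x)), replace=False)
            pred = self.forward_predict(x[idx])
            loss = self._loss(pred, y[idx])
            if not np.isfinite(loss.data):
                raise TrainingError(f"fine-tuning diverged at step {step}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        return losses

    # -- attribution ------------------------------------------------------

    def attention_score(self, sequence: np.ndarray) -> np.ndarray:
        """Mean attention weight onto each key position (sums to 1).

        Averaged over every encoder layer, head and query position; this is
        the per-scale importance profile of the filtration grid.
        """
        self.encode(sequence)
        stacks = [layer.attn.last_weights for layer in self.encoder]
        all_w = np.stack(stacks)  # (layers, B, heads, T, T)
        return all_w.mean(axis=(0, 1, 2, 3))

    def saliency(self, sequence: np.ndarray) -> np.ndarray:
        """|d prediction / d input| with the input's (T, 143, 6) shape."""
        c = self.config
        x = np.asarray(sequence, dtype=float).reshape(1, c.seq_len, c.n_features)
        leaf = Tensor(x, requires_grad=True)
        pred = self.forward_predict(leaf)
        pred.sum().backward()
        return np.abs(leaf.grad[0]).reshape(c.seq_len, c.n_combos, c.n_statistics)

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TopologicalSequenceModel":
        path = Path(path)
        config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(config)
        arrays = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.params()):
            p.data = arrays[f"p{i}"]
        return model
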