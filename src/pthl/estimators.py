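"""scikit-learn estimator interfaces over the embedding and the model.

`TopologicalEmbedder` is a transformer: a list of molecular complexes (or
pre-cut regions) goes in, the stacked (n, T, 143, 6) topological-sequence
tensor comes out. `TopologicalSequenceRegressor` wraps the transformer
model as a regressor with optional self-supervised pretraining before the
supervised fit. Both compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .embedding import ElementScheme, FiltrationSchedule, embed_complex, preset
from .model.transformer import ModelConfig, TopologicalSequenceModel
from .structure import ComplexRegion, MolecularComplex


class TopologicalEmbedder(BaseEstimator, TransformerMixin):
    """Featurize protein-ligand complexes into topological sequences.

    Parameters
    ----------
    preset : "large" or "small"
        Region cutoff and filtration schedule preset (20 A / 0->10 by 0.1,
        or 12 A / 2->12 by 0.2). Individual fields can be overridden.
    cutoff, start, stop, step : float, optional
        Explicit overrides of the preset values.
    flatten : bool
        If True, transform returns a 2D (n, T*143*6) array for direct use
        in sklearn pipelines; otherwise the (n, T, 143, 6) tensor.
    """

    def __init__(self, preset: str = "small", cutoff: float | None = None,
                 start: float | None = None, stop: float | None = None,
                 step: float | None = None, flatten: bool = False) -> None:
        self.preset = preset
        self.cutoff = cutoff
        self.start = start
        self.stop = stop
        self.step = step
        self.flatten = flatten

    def fit(self, X=None, y=None) -> "TopologicalEmbedder":
        base_cutoff, base_schedule = preset(self.preset)
        self.cutoff_ = self.cutoff if self.cutoff is not None else base_cutoff
        self.schedule_ = FiltrationSchedule(
            start=self.start if self.start is not None else base_schedule.start,
            stop=self.stop if self.stop is not None else base_schedule.stop,
            step=self.step if self.step is not None else base_schedule.step,
        )
        self.scheme_ = ElementScheme()
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "schedule_")
        if isinstance(X, (MolecularComplex, ComplexRegion)):
            X = [X]
        tensors = [
            embed_complex(item, schedule=self.schedule_, scheme=self.scheme_,
                          cutoff=self.cutoff_).tensor
            for item in X
        ]
        out = np.stack(tensors)
        if self.flatten:
            out = out.reshape(len(tensors), -1)
        return out

    def embed(self, item):
        """Full :class:`TopologicalSequence` (with metadata) for one complex."""
        check_is_fitted(self, "schedule_")
        return embed_complex(item, schedule=self.schedule_, scheme=self.scheme_,
                             cutoff=self.cutoff_)


class TopologicalSequenceRegressor(BaseEstimator, RegressorMixin):
    """Transformer regression over topological sequences.

    ``fit(X, y)`` takes X of shape (n, T, 143, 6) (or flattened per step)
    and scalar labels (binding affinities in -log Kd/Ki units), optionally
    runs masked-reconstruction pretraining on X first, then fine-tunes a
    regression head on the first-position encoder output. Seeded runs are
    bit-reproducible.
    """

    def __init__(self, d_model: int = 32, n_heads: int = 2,
                 n_encoder_layers: int = 2, n_decoder_layers: int = 1,
                 d_hidden: int | None = None, d_ff: int | None = None,
                 learning_rate: float = 1e-3, pretrain_steps: int = 0,
                 finetune_steps: int = 200, batch_size: int = 8,
                 mask_ratio: float = 0.5, loss: str = "mse", seed: int = 0) -> None:
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_encoder_layers = n_encoder_layers
        self.n_decoder_layers = n_decoder_layers
        self.d_hidden = d_hidden
        self.d_ff = d_ff
        self.learning_rate = learning_rate
        self.pretrain_steps = pretrain_steps
        self.finetune_steps = finetune_steps
        self.batch_size = batch_size
        self.mask_ratio = mask_ratio
        self.loss = loss
        self.seed = seed

    def _shape_config(self, X: np.ndarray) -> ModelConfig:
        X = np.asarray(X, dtype=float)
        if X.ndim == 4:
            _, t, c, s = X.shape
        elif X.ndim == 3:
            _, t, f = X.shape
            c, s = f, 1
        else:
            raise ValueError("X must be (n, T, 143, 6) or (n, T, features)")
        return ModelConfig(
            seq_len=t, n_combos=c, n_statistics=s,
            d_model=self.d_model, n_heads=self.n_heads,
            n_encoder_layers=self.n_encoder_layers,
            n_decoder_layers=self.n_decoder_layers,
            d_hidden=self.d_hidden, d_ff=self.d_ff,
            learning_rate=self.learning_rate, mask_ratio=self.mask_ratio,
            loss=self.loss, seed=self.seed,
        )

    def fit(self, X, y) -> "TopologicalSequenceRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        config = self._shape_config(X)
        self.model_ = TopologicalSequenceModel(config)
        flat = X.reshape(X.shape[0], config.seq_len, config.n_features)
        self.pretrain_history_ = (
            self.model_.pretrain(flat, steps=self.pretrain_steps,
                                 batch_size=self.batch_size)
            if self.pretrain_steps else []
        )
        self.finetune_history_ = self.model_.finetune(
            flat, y, steps=self.finetune_steps, batch_size=self.batch_size)
        self.n_features_in_ = config.n_features
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        c = self.model_.config
        flat = X.reshape(X.shape[0], c.seq_len, c.n_features)
        return self.model_.predict(flat)

    def attention_score(self, sequence) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.attention_score(np.asarray(sequence, dtype=float))

    def saliency(self, sequence) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.saliency(np.asarray(sequence, dtype=float))
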