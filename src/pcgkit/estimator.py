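"""Scikit-learn estimator interface for the spectrogram classifier.

``CVTTransClassifier`` wraps :class:`pcgkit.model.CVTNet` with SGD
training so it composes with sklearn pipelines and model selection.
``X`` is an array of RGB spectrogram images with shape (n_samples, H, W, 3)
and values in [0, 1]; ``y`` is any label array.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.validation import check_is_fitted

from .model import ModelConfig, CVTNet
from .nn.autodiff import cross_entropy


class _SGD:
    """Plain SGD with classical momentum."""

    def __init__(self, params, lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= (self.lr * v).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class CVTTransClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional vision transformer classifier over spectrogram images.

    Parameters
    ----------
    input_size : int
        Square image edge in pixels; must be divisible by 32.
    stage_widths, convs_per_stage : tuple
        Backbone channel widths and conv counts per stage (17 convs total
        in the full profile).
    embed_dim, heads, encoder_depth, ffn_hidden, head_hidden : int
        Transformer and head dimensions.
    lr, momentum, batch_size, epochs, max_steps : training schedule.
        The learning rate follows a cosine decay from ``lr`` to zero over
        the scheduled number of steps.
    validation_fraction : float
        Per-class fraction of the training set held out for the validation
        curve in ``history_`` (0 disables).
    random_state : int
        Seeds parameter initialization, shuffling, and the validation split.
    """

    def __init__(
        self,
        input_size: int = 64,
        stage_widths: tuple = (8, 16, 32, 64, 128, 256),
        convs_per_stage: tuple = (2, 2, 3, 3, 3, 4),
        embed_dim: int = 256,
        heads: int = 8,
        encoder_depth: int = 1,
        ffn_hidden: int = 512,
        head_hidden: int = 512,
        lr: float = 0.01,
        momentum: float = 0.9,
        batch_size: int = 16,
        epochs: int = 20,
        max_steps: int = 2000,
        validation_fraction: float = 0.0,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.stage_widths = stage_widths
        self.convs_per_stage = convs_per_stage
        self.embed_dim = embed_dim
        self.heads = heads
        self.encoder_depth = encoder_depth
        self.ffn_hidden = ffn_hidden
        self.head_hidden = head_hidden
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_steps = max_steps
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _model_config(self, num_classes: int) -> ModelConfig:
        return ModelConfig(
            input_size=self.input_size,
            stage_widths=tuple(self.stage_widths),
            convs_per_stage=tuple(self.convs_per_stage),
            embed_dim=self.embed_dim,
            heads=self.heads,
            encoder_depth=self.encoder_depth,
            ffn_hidden=self.ffn_hidden,
            head_hidden=self.head_hidden,
            num_classes=num_classes,
            seed=self.random_state,
        )

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("X must have shape (n_samples, H, W, 3)")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"images must be {self.input_size}x{self.input_size}, "
                f"got {X.shape[1]}x{X.shape[2]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains NaN/Inf")
        return X

    def fit(self, X, y):
        """Train with momentum SGD and cosine learning-rate decay."""
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self._encoder = LabelEncoder().fit(y)
        self.classes_ = self._encoder.classes_
        yi = self._encoder.transform(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes to fit")

        rng = np.random.default_rng(self.random_state)
        n = len(X)
        val_idx = np.array([], dtype=int)
        if self.validation_fraction > 0:
            val_parts = []
            for c in range(len(self.classes_)):
                idx_c = np.flatnonzero(yi == c)
                k = max(1, int(round(self.validation_fraction * idx_c.size)))
                val_parts.append(rng.permutation(idx_c)[:k])
            val_idx = np.concatenate(val_parts)
        train_idx = np.setdiff1d(np.arange(n), val_idx)

        self.model_ = CVTNet(self._model_config(len(self.classes_)))
        opt = _SGD(self.model_.parameters(), self.lr, self.momentum)
        steps_per_epoch = max(1, int(np.ceil(train_idx.size / self.batch_size)))
        total_steps = min(self.epochs * steps_per_epoch, self.max_steps)

        history = {"epoch": [], "train_loss": [], "train_acc": [],
                   "val_loss": [], "val_acc": []}
        step = 0
        for epoch in range(self.epochs):
            if step >= total_steps:
                break
            order = rng.permutation(train_idx)
            losses, hits, seen = [], 0, 0
            for s in range(0, order.size, self.batch_size):
                if step >= total_steps:
                    break
                batch = order[s : s + self.batch_size]
                if batch.size < 2:
                    continue  # BatchNorm needs more than one sample
                logits = self.model_.forward_logits(X[batch], training=True)
                loss = cross_entropy(logits, yi[batch])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"training diverged (loss={float(loss.data)}) at step {step}"
                    )
                opt.zero_grad()
                loss.backward()
                # cosine decay from the base rate to zero
                opt.lr = self.lr * 0.5 * (1 + np.cos(np.pi * step / max(total_steps, 1)))
                opt.step()
                losses.append(float(loss.data))
                hits += int((logits.data.argmax(axis=1) == yi[batch]).sum())
                seen += batch.size
                step += 1
            history["epoch"].append(epoch)
            history["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
            history["train_acc"].append(hits / seen if seen else np.nan)
            if val_idx.size:
                vlogits = self.model_.forward_logits(X[val_idx], training=False)
                vloss = cross_entropy(vlogits, yi[val_idx])
                history["val_loss"].append(float(vloss.data))
                history["val_acc"].append(
                    float((vlogits.data.argmax(axis=1) == yi[val_idx]).mean())
                )
            else:
                history["val_loss"].append(np.nan)
                history["val_acc"].append(np.nan)
        self.history_ = history
        self.n_features_in_ = X[0].size
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        # batch the forward pass to bound memory
        out = []
        for s in range(0, len(X), 64):
            out.append(self.model_.forward(X[s : s + 64]))
        return np.vstack(out)

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]
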