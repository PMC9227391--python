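"""The two-branch (pseudo-Siamese) 1D convolutional spectral classifier.

Architecture: each of the two inputs — the pure-compound spectrum and the
mixture spectrum — passes through its own stack of ``n_conv_layers``
convolutional layers (32 kernels of size 5, ReLU, "same" padding), each
followed by a max-pooling layer of stride 2.  The branches share their
architecture but never their weights: pure and mixture spectra come from
different distributions, so each branch learns its own filters.  The two
feature maps are concatenated along the channel axis, flattened
(channel-major), passed through a dense layer of 100 ReLU units with
dropout 0.2, and a final one-unit sigmoid dense layer outputs the
probability that the mixture contains the compound.  Training minimizes
binary cross-entropy with Adam.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .augment import SpectralPair, substream
from .nn import Adam, ConvLayer, Dense, Dropout, MaxPool, bce_with_logits, sigmoid

__all__ = ["ModelConfig", "PSCNN", "build_pscnn", "train", "predict_pair",
           "TrainingError", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Model configuration incompatible with the input length."""


class TrainingError(RuntimeError):
    """Training preconditions violated (e.g. single-class data)."""


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the optimized settings (depth 6, lr 1e-4).

    ``epochs`` defaults to 100, the point past which training is stable on
    the augmented dataset.
    """

    n_conv_layers: int = 6
    n_kernels: int = 32
    kernel_size: int = 5
    pool_size: int = 2
    dense_units: int = 100
    dropout_rate: float = 0.2
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_conv_layers", "n_kernels", "kernel_size", "pool_size",
                     "dense_units", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _branch(config: ModelConfig, rng: np.random.Generator) -> list:
    layers: list = []
    c_in = 1
    for _ in range(config.n_conv_layers):
        layers.append(ConvLayer(c_in, config.n_kernels, config.kernel_size, rng))
        layers.append(MaxPool(config.pool_size))
        c_in = config.n_kernels
    layers[0].skip_input_grad = True  # gradient wrt the spectrum itself is unused
    return layers


class PSCNN:
    """Two independent conv/pool branches plus a dense comparison head."""

    def __init__(self, config: ModelConfig, input_length: int):
        length = input_length
        for _ in range(config.n_conv_layers):
            length //= config.pool_size
        if length < 1:
            raise ConfigurationError(
                f"input length {input_length} too short for "
                f"{config.n_conv_layers} pooling stages; need at least "
                f"{config.pool_size ** config.n_conv_layers} points"
            )
        self.config = config
        self.input_length = input_length
        self.feature_length = length
        init = np.random.default_rng(substream(config.seed, "weights"))
        self.branch_pure = _branch(config, init)
        self.branch_mix = _branch(config, init)
        n_features = 2 * config.n_kernels * length
        self.dense1 = Dense(n_features, config.dense_units, init, relu=True)
        self.dropout = Dropout(config.dropout_rate)
        self.dense2 = Dense(config.dense_units, 1, init, relu=False)
        self.history: dict[str, list[float]] = {}
        self._drop_rng = np.random.default_rng(substream(config.seed, "dropout"))

    # -- forward / backward -------------------------------------------------

    def _check_length(self, x: np.ndarray) -> None:
        if x.shape[1] != self.input_length:
            raise ValueError(
                f"input length {x.shape[1]} does not match model grid "
                f"({self.input_length} points)"
            )

    def forward(self, x_pure: np.ndarray, x_mix: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch; inputs are (B, L) float arrays."""
        self._check_length(x_pure)
        self._check_length(x_mix)
        dtype = self.dense1.w.dtype
        # length-major activations: (L, B, 1)
        h1 = np.ascontiguousarray(np.asarray(x_pure, dtype=dtype).T)[:, :, None]
        h2 = np.ascontiguousarray(np.asarray(x_mix, dtype=dtype).T)[:, :, None]
        for layer in self.branch_pure:
            h1 = layer.forward(h1, train=train)
        for layer in self.branch_mix:
            h2 = layer.forward(h2, train=train)
        h = np.concatenate([h1, h2], axis=2)            # (L', B, 2*C)
        b = h.shape[1]
        self._head_shape = h.shape
        # flatten channel-major: feature index = channel * L' + position
        flat = np.ascontiguousarray(h.transpose(1, 2, 0)).reshape(b, -1)
        z = self.dense1.forward(flat, train=train)
        z = self.dropout.forward(z, train=train, rng=self._drop_rng)
        return self.dense2.forward(z, train=train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.dense2.backward(np.asarray(dlogits)[:, None])
        d = self.dropout.backward(d)
        d = self.dense1.backward(d)
        lp, b, c2 = self._head_shape
        d = d.reshape(b, c2, lp).transpose(2, 0, 1)  # back to (L', B, 2*C)
        c = c2 // 2
        d1, d2 = np.ascontiguousarray(d[:, :, :c]), np.ascontiguousarray(d[:, :, c:])
        for layer in reversed(self.branch_pure):
            d1 = layer.backward(d1)
        for layer in reversed(self.branch_mix):
            d2 = layer.backward(d2)

    def params(self) -> list:
        out = []
        for layer in (*self.branch_pure, *self.branch_mix, self.dense1, self.dense2):
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    # -- inference ----------------------------------------------------------

    def predict(self, x_pure: np.ndarray, x_mix: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Inclusion probabilities in [0, 1], one per row."""
        probs = []
        for start in range(0, x_pure.shape[0], batch_size):
            z = self.forward(x_pure[start:start + batch_size],
                             x_mix[start:start + batch_size], train=False)
            probs.append(sigmoid(z))
        return np.concatenate(probs)

    # -- training -----------------------------------------------------------

    def fit(
        self,
        train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
        val_data: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
        verbose: bool = False,
    ) -> dict[str, list[float]]:
        """Run ``config.epochs`` epochs of minibatch Adam; records history.

        ``train_data``/``val_data`` are (pure, mixture, labels) arrays.
        """
        xp, xm, y = train_data
        if xp.shape[0] == 0:
            raise TrainingError("empty training set")
        if len(np.unique(y)) < 2:
            raise TrainingError("training data contain a single class")
        cfg = self.config
        opt = Adam(cfg.learning_rate)
        shuffle_rng = np.random.default_rng(substream(cfg.seed, "shuffle"))
        self.history = {"loss": [], "acc": [], "val_loss": [], "val_acc": []}
        for epoch in range(cfg.epochs):
            order = shuffle_rng.permutation(xp.shape[0])
            losses, correct = [], 0
            for start in range(0, order.size, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self.forward(xp[idx], xm[idx], train=True)
                loss, dlogits = bce_with_logits(logits, y[idx])
                self.backward(dlogits)
                opt.step(self.params())
                losses.append(loss * idx.size)
                correct += int(np.sum((logits > 0) == (y[idx] > 0.5)))
            self.history["loss"].append(float(np.sum(losses) / order.size))
            self.history["acc"].append(correct / order.size)
            if val_data is not None:
                vl, va = self.evaluate(val_data)
                self.history["val_loss"].append(vl)
                self.history["val_acc"].append(va)
            if verbose:  # pragma: no cover - logging only
                msg = (f"epoch {epoch + 1}/{cfg.epochs} "
                       f"loss={self.history['loss'][-1]:.4f} acc={self.history['acc'][-1]:.4f}")
                if val_data is not None:
                    msg += (f" val_loss={self.history['val_loss'][-1]:.4f}"
                            f" val_acc={self.history['val_acc'][-1]:.4f}")
                print(msg, flush=True)
        return self.history

    def evaluate(self, data: tuple[np.ndarray, np.ndarray, np.ndarray]) -> tuple[float, float]:
        """(mean BCE loss, accuracy at threshold 0.5) on held-out arrays."""
        xp, xm, y = data
        logits = []
        for start in range(0, xp.shape[0], 128):
            logits.append(self.forward(xp[start:start + 128], xm[start:start + 128]))
        z = np.concatenate(logits)
        loss, _ = bce_with_logits(z, y)
        acc = float(np.mean((z > 0) == (y > 0.5)))
        return loss, acc

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write config.json, weights.npz and history.json into a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "config.json").write_text(
            json.dumps({"model": asdict(self.config), "input_length": self.input_length}, indent=2)
        )
        arrays = {}
        for i, (p, _) in enumerate(self.params()):
            arrays[f"p{i:03d}"] = p
        np.savez(path / "weights.npz", **arrays)
        (path / "history.json").write_text(json.dumps(self.history))

    @classmethod
    def load(cls, path: str | Path) -> "PSCNN":
        path = Path(path)
        blob = json.loads((path / "config.json").read_text())
        model = cls(ModelConfig(**blob["model"]), blob["input_length"])
        with np.load(path / "weights.npz") as data:
            for i, (p, _) in enumerate(model.params()):
                saved = data[f"p{i:03d}"]
                if saved.shape != p.shape:
                    raise ValueError(f"checkpoint shape mismatch at parameter {i}")
                p[...] = saved
        hist = path / "history.json"
        if hist.exists():
            model.history = json.loads(hist.read_text())
        return model


# ---------------------------------------------------------------------------
# module-level conveniences mirroring the pipeline vocabulary


def build_pscnn(config: ModelConfig, input_length: int) -> PSCNN:
    """Construct an untrained two-branch model for spectra of ``input_length``."""
    return PSCNN(config, input_length)


def train(
    model: PSCNN,
    train_data,
    val_data=None,
    verbose: bool = False,
) -> PSCNN:
    """Fit ``model`` on (pure, mixture, label) arrays or lists of pairs."""
    model.fit(_as_arrays(train_data), None if val_data is None else _as_arrays(val_data),
              verbose=verbose)
    return model


def _as_arrays(data):
    if isinstance(data, tuple):
        return data
    xp = np.stack([p.pure.intensities for p in data]).astype(np.float32)
    xm = np.stack([p.mixture.intensities for p in data]).astype(np.float32)
    y = np.array([p.label for p in data], dtype=np.float32)
    return xp, xm, y


def predict_pair(model: PSCNN, pair: SpectralPair) -> float:
    """Probability that the pair's mixture contains the pair's pure compound."""
    return float(
        model.predict(
            pair.pure.intensities[None, :].astype(np.float32),
            pair.mixture.intensities[None, :].astype(np.float32),
        )[0]
    )


def predict_pairs(model: PSCNN, pairs: list[SpectralPair]) -> np.ndarray:
    xp, xm, _ = _as_arrays(pairs)
    return model.predict(xp, xm)
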