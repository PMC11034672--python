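"""Masked LSTM sequence classifier, trained with Adam on cross-entropy.

Architecture: masking -> LSTM(64) -> dense(2) -> softmax. A timestep is
masked (skipped, carrying the recurrent state through) when every feature
equals the mask value, which is the padding value 0 — so the classifier
reads exactly the ``true_length`` genuine timesteps of each padded
sequence, regardless of how much trailing padding follows.

The network, backpropagation through time, and the Adam optimizer are
implemented directly on NumPy arrays, vectorized over the batch; the
input projection for all timesteps is computed as a single matrix product
per pass, leaving only the recurrent product inside the time loop. Packed
gate order is (input, forget, output, candidate) so the three sigmoid
gates occupy one contiguous block. Weights are initialized Glorot-uniform
(input kernel, dense head) and orthogonal per gate (recurrent kernel),
with the forget-gate bias at 1. All randomness (initialization, epoch
shuffling) flows from the config seed, so identical config + data
reproduce identical training runs. ``dtype`` selects float32 (fast,
default) or float64 (used by e.g. finite-difference gradient checks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "ModelConfig",
    "ClassifierModel",
    "TrainHistory",
    "DivergenceError",
    "softmax",
    "cross_entropy",
    "build_model",
    "train",
    "predict_proba",
    "predict_label",
    "save_model",
    "load_model",
]

_FEATURES_BY_MODE = {"two_feature": 2, "four_feature": 4}
_EPS_CLIP = 1e-12


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class ModelConfig:
    lstm_units: int = 64
    learning_rate: float = 0.001
    epochs: int = 240
    mask_value: float = 0.0
    batch_size: int = 32
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.lstm_units < 1:
            raise ValueError("lstm_units must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)  # per-epoch mean cross-entropy
    accuracy: list = field(default_factory=list)  # per-epoch binary accuracy


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, overflow-safe via max-shift."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean categorical cross-entropy -sum_c y_c log p_c over the batch.

    Probabilities are clipped below at 1e-12 for numerical stability.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: labels {y.shape} vs probabilities {p.shape}")
    return float(-(y * np.log(np.clip(p, _EPS_CLIP, None))).sum(axis=-1).mean())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal_gates(rng: np.random.Generator, units: int, n_gates: int) -> np.ndarray:
    blocks = []
    for _ in range(n_gates):
        a = rng.normal(size=(units, units))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))  # fix QR sign ambiguity
        blocks.append(q)
    return np.concatenate(blocks, axis=1)


class ClassifierModel:
    """Masking + LSTM + softmax classifier over (N, T, F) sequence batches.

    Output rows are probability pairs (p_TD, p_ASD) matching the one-hot
    label convention TD = (1, 0), ASD = (0, 1).
    """

    def __init__(self, cfg: ModelConfig, feature_mode: str):
        if feature_mode not in _FEATURES_BY_MODE:
            raise ValueError(f"unknown feature mode {feature_mode!r}")
        self.cfg = cfg
        self.feature_mode = feature_mode
        self.n_features = _FEATURES_BY_MODE[feature_mode]
        h = cfg.lstm_units
        dt = cfg.np_dtype
        rng = np.random.default_rng(cfg.seed)
        self.params = {
            "Wx": _glorot(rng, self.n_features, 4 * h).astype(dt),
            "Wh": _orthogonal_gates(rng, h, 4).astype(dt),
            "b": np.zeros(4 * h, dtype=dt),
            "Wd": _glorot(rng, h, 2).astype(dt),
            "bd": np.zeros(2, dtype=dt),
        }
        self.params["b"][h : 2 * h] = 1.0  # forget-gate bias

    # ---------------------------------------------------------------- forward

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.cfg.np_dtype)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise ValueError(
                f"expected (N, T, {self.n_features}) input for mode "
                f"{self.feature_mode!r}, got shape {X.shape}"
            )
        return X

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """Run the network; returns (probabilities, cache)."""
        X = self._check_input(X)
        p = self.params
        B, T, _ = X.shape
        H = self.cfg.lstm_units
        mask = ~np.all(X == self.cfg.mask_value, axis=2)  # True = genuine step
        any_step = np.flatnonzero(mask.any(axis=0))
        t_eff = int(any_step[-1]) + 1 if any_step.size else 0

        # input projection for every timestep in one product
        zx = X[:, :t_eff].reshape(B * t_eff, -1) @ p["Wx"] + p["b"]
        zx = zx.reshape(B, t_eff, 4 * H)

        h = np.zeros((B, H), dtype=X.dtype)
        c = np.zeros((B, H), dtype=X.dtype)
        steps = []
        for t in range(t_eff):
            z = zx[:, t] + h @ p["Wh"]
            gates = np.empty_like(z)
            gates[:, : 3 * H] = _sigmoid(z[:, : 3 * H])  # i, f, o
            gates[:, 3 * H :] = np.tanh(z[:, 3 * H :])  # candidate g
            i = gates[:, :H]
            f = gates[:, H : 2 * H]
            o = gates[:, 2 * H : 3 * H]
            g = gates[:, 3 * H :]
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            m = mask[:, t][:, None]
            h_next = np.where(m, h_new, h)
            c_next = np.where(m, c_new, c)
            if want_cache:
                steps.append((gates, c, tanh_c, h, m))
            h, c = h_next, c_next

        logits = h @ p["Wd"] + p["bd"]
        probs = softmax(logits)
        if want_cache:
            cache = {"steps": steps, "h_final": h, "probs": probs,
                     "X": X, "t_eff": t_eff}
            return probs, cache
        return probs, None

    # --------------------------------------------------------------- backward

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray):
        """Mean cross-entropy over the batch and its parameter gradients."""
        Y = np.asarray(Y, dtype=self.cfg.np_dtype)
        probs, cache = self.forward(X, want_cache=True)
        loss = cross_entropy(Y, probs)

        p = self.params
        X = cache["X"]
        t_eff = cache["t_eff"]
        B = X.shape[0]
        H = self.cfg.lstm_units
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = ((probs - Y) / B).astype(X.dtype)
        grads["Wd"] = cache["h_final"].T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dh = dlogits @ p["Wd"].T
        dc = np.zeros((B, H), dtype=X.dtype)

        dZ = np.zeros((B, t_eff, 4 * H), dtype=X.dtype)
        for t in range(t_eff - 1, -1, -1):
            gates, c_prev, tanh_c, h_prev, m = cache["steps"][t]
            i = gates[:, :H]
            f = gates[:, H : 2 * H]
            o = gates[:, 2 * H : 3 * H]
            g = gates[:, 3 * H :]

            dh_new = dh * m
            dh_skip = dh - dh_new
            dc_new = dc * m
            dc_skip = dc - dc_new

            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * o * (1.0 - tanh_c**2)
            dc = dc_new * f + dc_skip

            dz = dZ[:, t]
            dz[:, :H] = dc_new * g * i * (1.0 - i)
            dz[:, H : 2 * H] = dc_new * c_prev * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = do * o * (1.0 - o)
            dz[:, 3 * H :] = dc_new * i * (1.0 - g**2)
            grads["Wh"] += h_prev.T @ dz
            dh = dz @ p["Wh"].T + dh_skip

        dZ_flat = dZ.reshape(B * t_eff, 4 * H)
        grads["Wx"] = X[:, :t_eff].reshape(B * t_eff, -1).T @ dZ_flat
        grads["b"] = dZ_flat.sum(axis=0)
        return loss, grads, probs


def build_model(cfg: ModelConfig, feature_mode: str) -> ClassifierModel:
    return ClassifierModel(cfg, feature_mode)


def _binary_accuracy(Y: np.ndarray, probs: np.ndarray) -> float:
    pred_asd = probs[:, 1] >= 0.5
    true_asd = Y[:, 1] == 1.0
    return float(np.mean(pred_asd == true_asd))


def train(model: ClassifierModel, X, Y=None, cfg: ModelConfig | None = None) -> TrainHistory:
    """Train ``model`` in place with Adam; returns the per-epoch history.

    ``X`` may be a :class:`~dragtraj.kinematics.FeatureTensor` (labels taken
    from it) or an (N, T, F) array with ``Y`` the (N, 2) one-hot labels.
    """
    if hasattr(X, "sequences"):
        Y = X.labels
        X = X.sequences
    cfg = cfg or model.cfg
    X = np.asarray(X, dtype=cfg.np_dtype)
    Y = np.asarray(Y, dtype=cfg.np_dtype)
    rng = np.random.default_rng(cfg.seed + 1)  # decoupled from init stream

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-7
    step = 0

    n = X.shape[0]
    history = TrainHistory()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads, probs = model.loss_and_grads(X[idx], Y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            epoch_correct += _binary_accuracy(Y[idx], probs) * len(idx)
            step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k, grad in grads.items():
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grad
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grad**2
                model.params[k] -= (lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)).astype(
                    model.params[k].dtype
                )
        history.loss.append(epoch_loss / n)
        history.accuracy.append(epoch_correct / n)
    return history


def predict_proba(model: ClassifierModel, X, batch_size: int = 256) -> np.ndarray:
    """(N, 2) probability pairs (p_TD, p_ASD); rows sum to 1."""
    if hasattr(X, "sequences"):
        X = X.sequences
    X = np.asarray(X, dtype=model.cfg.np_dtype)
    if X.ndim == 2:
        X = X[None]
    out = np.empty((X.shape[0], 2))
    for start in range(0, X.shape[0], batch_size):
        out[start : start + batch_size] = model.forward(X[start : start + batch_size])[0]
    return out


def predict_label(model: ClassifierModel, X, threshold: float = 0.5) -> list:
    """Group labels; a trajectory is called ASD when p_ASD >= threshold."""
    probs = predict_proba(model, X)
    return ["ASD" if p >= threshold else "TD" for p in probs[:, 1]]


def save_model(model: ClassifierModel, path) -> None:
    """Checkpoint weights + config to a single ``.npz`` file."""
    meta = {"config": asdict(model.cfg), "feature_mode": model.feature_mode}
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_model(path) -> ClassifierModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        model = ClassifierModel(ModelConfig(**meta["config"]), meta["feature_mode"])
        for k in model.params:
            model.params[k] = data[k]
    return model
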