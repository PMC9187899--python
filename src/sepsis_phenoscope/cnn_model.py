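"""Seven-layer 1-D convolutional classifier over the 35-feature vector.

The network is seven valid (no padding) 1-D convolutions: the first six
use ReLU, the last uses a Sigmoid and must reduce the feature map to a
single channel of length 1, so the forward pass maps a 35-vector to one
probability.  The default schedule grows channels 1-8-16-16-32-32-16 with
kernel width 3 and finishes with a kernel spanning the remaining length
(23), giving a scalar output.  There is no pooling or normalization
layer.  Implemented directly on NumPy arrays with hand-derived backprop
and an Adam/SGD optimizer; everything is seeded and single-threaded, so
training is bit-reproducible.

Training minimizes binary cross-entropy with death (survived_28d = 0) as
the positive class.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURES_35

INPUT_LEN = 35


@dataclass
class CNNConfig:
    """Layer schedule and training hyperparameters.

    ``channels`` lists output channels of the 7 layers; ``kernels`` their
    widths; ``strides`` their strides.  The input is shaped 1 x 35 (a
    single-channel sequence of the 35 blood tests in canonical order).
    """

    channels: tuple[int, ...] = (8, 16, 16, 32, 32, 16, 1)
    kernels: tuple[int, ...] = (3, 3, 3, 3, 3, 3, 23)
    strides: tuple[int, ...] = (1, 1, 1, 1, 1, 1, 1)
    learning_rate: float = 1e-3
    epochs: int = 60
    batch_size: int = 64
    optimizer: str = "adam"
    weight_decay: float = 5e-3  # L2 on conv weights; the net is heavily
    # over-parameterized for small tabular cohorts and overfits without it
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.channels) == len(self.kernels) == len(self.strides) == 7):
            raise ValueError("the schedule must have exactly 7 convolution layers")
        if self.channels[-1] != 1:
            raise ValueError("the final layer must output a single channel")
        length = INPUT_LEN
        for i, (k, s) in enumerate(zip(self.kernels, self.strides)):
            if k > length:
                raise ValueError(
                    f"layer {i + 1}: kernel {k} exceeds remaining length {length}"
                )
            length = (length - k) // s + 1
        if length != 1:
            raise ValueError(
                f"schedule does not reduce the input to length 1 (got {length})"
            )


@dataclass
class CNNModel:
    config: CNNConfig
    weights: list[np.ndarray]  # per layer: (C_out, C_in, k)
    biases: list[np.ndarray]  # per layer: (C_out,)

    def parameter_count(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))


def build_network(config: CNNConfig) -> CNNModel:
    """Allocate a model with He-initialized ReLU layers and a
    Xavier-initialized output layer."""
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    c_in = 1
    for i, (c_out, k) in enumerate(zip(config.channels, config.kernels)):
        fan_in = c_in * k
        if i < 6:
            sd = np.sqrt(2.0 / fan_in)
        else:
            sd = np.sqrt(1.0 / fan_in)
        weights.append(rng.normal(0.0, sd, (c_out, c_in, k)))
        biases.append(np.zeros(c_out))
        c_in = c_out
    return CNNModel(config=config, weights=weights, biases=biases)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int):
    """x: (B, C_in, L); w: (C_out, C_in, k) -> (B, C_out, L_out)."""
    k = w.shape[2]
    l_out = (x.shape[2] - k) // stride + 1
    idx = np.arange(l_out)[:, None] * stride + np.arange(k)[None, :]
    cols = x[:, :, idx]  # (B, C_in, L_out, k)
    out = np.einsum("bclk,ock->bol", cols, w, optimize=True) + b[None, :, None]
    return out, (cols, idx, x.shape)


def _conv_backward(dout: np.ndarray, w: np.ndarray, cache):
    cols, idx, x_shape = cache
    dw = np.einsum("bol,bclk->ock", dout, cols, optimize=True)
    db = dout.sum(axis=(0, 2))
    dcols = np.einsum("bol,ock->bclk", dout, w, optimize=True)
    dx = np.zeros(x_shape)
    np.add.at(dx, (slice(None), slice(None), idx), dcols)
    return dx, dw, db


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    # keep the output in the open interval even when the logit saturates
    # in float64 (also protects the cross-entropy log)
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def forward_cnn(model: CNNModel, x: np.ndarray, caches: list | None = None) -> np.ndarray:
    """Probability of death for (n, 35) inputs; values strictly in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != INPUT_LEN:
        raise ValueError(f"expected {INPUT_LEN} features, got {x.shape[1]}")
    h = x[:, None, :]
    for i in range(7):
        z, cache = _conv_forward(h, model.weights[i], model.biases[i],
                                 model.config.strides[i])
        if i < 6:
            h = np.maximum(z, 0.0)
        else:
            h = _sigmoid(z)
        if caches is not None:
            caches.append((cache, z))
    return h[:, 0, 0]


def _backward_cnn(model: CNNModel, caches, dp: np.ndarray):
    """Gradients of all weights/biases given dL/d(sigmoid output)."""
    grads_w = [None] * 7
    grads_b = [None] * 7
    # output layer: sigmoid derivative folded in by the caller via dz
    dz = dp[:, None, None]  # (B, 1, 1): caller passes dL/dz directly
    for i in range(6, -1, -1):
        cache, z = caches[i]
        if i < 6:
            dz = dz * (z > 0)
        dx, dw, db = _conv_backward(dz, model.weights[i], cache)
        grads_w[i], grads_b[i] = dw, db
        dz = dx
    return grads_w, grads_b


def fit_cnn(
    train: pd.DataFrame | np.ndarray,
    labels: np.ndarray | None = None,
    config: CNNConfig | None = None,
) -> tuple[CNNModel, list[float]]:
    """Train on a normalized cohort table (or (n, 35) matrix + labels).

    Labels: 1 = death.  Returns the model and per-epoch BCE trace.
    """
    if config is None:
        config = CNNConfig()
    if isinstance(train, pd.DataFrame):
        x = train[list(FEATURES_35)].to_numpy(dtype=float)
        t = 1.0 - train["survived_28d"].to_numpy(dtype=float)
    else:
        x = np.asarray(train, dtype=float)
        if labels is None:
            raise ValueError("labels required with a raw feature matrix")
        t = np.asarray(labels, dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("training data contains a single class")
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)
    model = build_network(config)

    opt_m = [np.zeros_like(w) for w in model.weights] + [np.zeros_like(b) for b in model.biases]
    opt_v = [np.zeros_like(g) for g in opt_m]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            caches: list = []
            p = forward_cnn(model, x[idx], caches)
            ti = t[idx]
            e = 1e-12
            loss = float(-np.mean(ti * np.log(p + e) + (1 - ti) * np.log(1 - p + e)))
            total += loss * idx.size
            # BCE + sigmoid: dL/dz = (p - t)/B
            dz = (p - ti) / idx.size
            gw, gb = _backward_cnn(model, caches, dz)
            step += 1
            if config.weight_decay > 0:
                gw = [g + config.weight_decay * w for g, w in zip(gw, model.weights)]
            grads = gw + gb
            tensors = model.weights + model.biases
            for j, (w, g) in enumerate(zip(tensors, grads)):
                if config.optimizer == "sgd":
                    w -= config.learning_rate * g
                else:
                    opt_m[j] = beta1 * opt_m[j] + (1 - beta1) * g
                    opt_v[j] = beta2 * opt_v[j] + (1 - beta2) * g * g
                    mhat = opt_m[j] / (1 - beta1**step)
                    vhat = opt_v[j] / (1 - beta2**step)
                    w -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        trace.append(total / n)
    return model, trace


def predict_cnn(model: CNNModel, table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-patient (p_survive, p_death, predicted death label at 0.5)."""
    if isinstance(table, pd.DataFrame):
        x = table[list(FEATURES_35)].to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
    p_death = forward_cnn(model, x)
    return pd.DataFrame(
        {
            "p_survive": 1.0 - p_death,
            "p_death": p_death,
            "pred_death": (p_death > 0.5).astype(int),
        }
    )


def save_cnn(model: CNNModel, path: str | Path) -> None:
    """Portable archive: config JSON + one .npy per tensor, zipped."""
    path = Path(path)
    cfg = {
        "channels": list(model.config.channels),
        "kernels": list(model.config.kernels),
        "strides": list(model.config.strides),
        "learning_rate": model.config.learning_rate,
        "epochs": model.config.epochs,
        "batch_size": model.config.batch_size,
        "optimizer": model.config.optimizer,
        "weight_decay": model.config.weight_decay,
        "seed": model.config.seed,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(cfg, indent=2))
        import io

        for i, (w, b) in enumerate(zip(model.weights, model.biases)):
            for tag, arr in (("w", w), ("b", b)):
                buf = io.BytesIO()
                np.save(buf, arr)
                zf.writestr(f"layer{i}_{tag}.npy", buf.getvalue())


def load_cnn(path: str | Path) -> CNNModel:
    import io

    with zipfile.ZipFile(path) as zf:
        cfg = json.loads(zf.read("config.json"))
        config = CNNConfig(
            channels=tuple(cfg["channels"]),
            kernels=tuple(cfg["kernels"]),
            strides=tuple(cfg["strides"]),
            learning_rate=cfg["learning_rate"],
            epochs=cfg["epochs"],
            batch_size=cfg["batch_size"],
            optimizer=cfg["optimizer"],
            weight_decay=cfg.get("weight_decay", 0.0),
            seed=cfg["seed"],
        )
        weights, biases = [], []
        for i in range(7):
            weights.append(np.load(io.BytesIO(zf.read(f"layer{i}_w.npy"))))
            biases.append(np.load(io.BytesIO(zf.read(f"layer{i}_b.npy"))))
    return CNNModel(config=config, weights=weights, biases=biases)
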