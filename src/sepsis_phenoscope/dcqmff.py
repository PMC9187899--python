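"""The double-coefficient quadratic multivariate fitting function (DCQMFF).

A two-headed quadratic-expansion softmax classifier over 11 normalized
blood tests.  Each head sums L (default 33) channels; channel l of head 1
contributes

    b_l * ( a0_l + sum_i a_lin[l,i] x_i + sum_{i<=j} a_quad[l,ij] x_i x_j )

and head 2 is identical with coefficients (c, d).  The softmax of
(y1, y2) gives (p_survive, p_death).  The product b_l * a[l,.] is the
"double coefficient": the function class is exactly a quadratic logit
(collapse() materializes the equivalent 78-coefficient form), but the
factored parameterization trains each quadratic surface through a small
bottleneck of channel gains.

Training minimizes softmax cross-entropy by mini-batch gradient descent
(plain SGD or Adam) with analytic gradients of the product
parameterization:

    dL/db_l = g * (A phi)_l        dL/dA[l,k] = g * b_l * phi_k

where phi is the 78-term quadratic expansion and g = p1 - t1 is the
softmax residual of head 1 (and its negative for head 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURES_11

N_RAW = 11
#: expansion length: 1 intercept + 11 linear + 66 ordered-pair products
N_EXPANDED = 1 + N_RAW + N_RAW * (N_RAW + 1) // 2

# index pairs (i, j), i <= j, in fixed row-major order
_PAIRS = [(i, j) for i in range(N_RAW) for j in range(i, N_RAW)]


def quad_features(x: np.ndarray) -> np.ndarray:
    """Quadratic expansion [1, x_1..x_11, x_i x_j for i <= j] (length 78).

    Accepts a single 11-vector or an (n, 11) matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != N_RAW:
        raise ValueError(f"expected {N_RAW} features, got {x.shape[1]}")
    n = x.shape[0]
    out = np.empty((n, N_EXPANDED))
    out[:, 0] = 1.0
    out[:, 1 : 1 + N_RAW] = x
    for k, (i, j) in enumerate(_PAIRS):
        out[:, 1 + N_RAW + k] = x[:, i] * x[:, j]
    return out[0] if single else out


@dataclass
class DCQMFFParams:
    """Parameter bundle: channel gains (b, c) and per-channel quadratic
    coefficient rows (a, d), one (L, 78) matrix per head.

    Row layout of a/d: [intercept, 11 linear terms, 66 pair terms]."""

    b: np.ndarray  # (L,)
    a: np.ndarray  # (L, 78) head 1
    c: np.ndarray  # (L,)
    d: np.ndarray  # (L, 78) head 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        L = self.b.shape[0]
        for name, arr, shape in (
            ("b", self.b, (L,)),
            ("a", self.a, (L, N_EXPANDED)),
            ("c", self.c, (L,)),
            ("d", self.d, (L, N_EXPANDED)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")

    @property
    def L(self) -> int:
        return int(self.b.shape[0])

    @classmethod
    def init_random(cls, L: int = 33, seed: int = 0) -> "DCQMFFParams":
        """Gaussian init scaled to keep initial logits O(1):
        gains ~ N(0, 1/sqrt(L)), coefficient rows ~ N(0, 1/sqrt(78))."""
        rng = np.random.default_rng(seed)
        return cls(
            b=rng.normal(0.0, L**-0.5, L),
            a=rng.normal(0.0, N_EXPANDED**-0.5, (L, N_EXPANDED)),
            c=rng.normal(0.0, L**-0.5, L),
            d=rng.normal(0.0, N_EXPANDED**-0.5, (L, N_EXPANDED)),
            seed=seed,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "L": self.L,
            "seed": self.seed,
            "b": self.b.tolist(),
            "a": self.a.tolist(),
            "c": self.c.tolist(),
            "d": self.d.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DCQMFFParams":
        p = json.loads(Path(path).read_text())
        params = cls(b=p["b"], a=p["a"], c=p["c"], d=p["d"], seed=p.get("seed", 0))
        if params.L != p["L"]:
            raise ValueError("channel count mismatch in serialized params")
        return params


@dataclass
class DCQMFFConfig:
    L: int = 33
    learning_rate: float = 1e-2
    epochs: int = 500
    batch_size: int = 64
    optimizer: str = "adam"  # or "sgd"
    seed: int = 0
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.learning_rate <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate and epochs must be positive")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _logits(params: DCQMFFParams, phi: np.ndarray) -> np.ndarray:
    """(n, 2) array of head logits for pre-expanded inputs."""
    y1 = (phi @ params.a.T) @ params.b
    y2 = (phi @ params.d.T) @ params.c
    return np.stack([y1, y2], axis=1)


def _softmax2(y: np.ndarray) -> np.ndarray:
    m = y.max(axis=1, keepdims=True)
    e = np.exp(y - m)
    return e / e.sum(axis=1, keepdims=True)


def forward(params: DCQMFFParams, x: np.ndarray) -> np.ndarray:
    """(p_survive, p_death) for one 11-vector or an (n, 11) matrix.

    Numerically stable (max-subtracted softmax); the pair sums to 1 to
    machine precision.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    phi = quad_features(x if not single else x[None, :])
    p = _softmax2(_logits(params, phi))
    return p[0] if single else p


def collapse(params: DCQMFFParams) -> tuple[np.ndarray, np.ndarray]:
    """The equivalent single-coefficient quadratic logit per head.

    Returns (w1, w2), each of length 78 with w_k = sum_l gain_l * row[l, k];
    forward() on the collapsed form reproduces the double form exactly.
    """
    return params.a.T @ params.b, params.d.T @ params.c


def forward_collapsed(w1: np.ndarray, w2: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Softmax pair from collapsed coefficient vectors (for the identity
    check against :func:`forward`)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    phi = quad_features(x if not single else x[None, :])
    y = np.stack([phi @ w1, phi @ w2], axis=1)
    p = _softmax2(y)
    return p[0] if single else p


def loss_and_gradients(
    params: DCQMFFParams, phi: np.ndarray, t_death: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and its analytic gradients on one batch.

    ``t_death`` is 1 for death, 0 for survival (head 1 is the survival
    head, so its target is 1 - t_death).
    """
    n = phi.shape[0]
    y = _logits(params, phi)
    p = _softmax2(y)
    t1 = 1.0 - t_death
    eps = 1e-12
    loss = float(-np.mean(t1 * np.log(p[:, 0] + eps) + t_death * np.log(p[:, 1] + eps)))
    # softmax-CE residuals per head
    g1 = (p[:, 0] - t1) / n  # dL/dy1
    g2 = (p[:, 1] - t_death) / n
    s1 = phi @ params.a.T  # (n, L): channel sums of head 1
    s2 = phi @ params.d.T
    grads = {
        "b": g1 @ s1,
        "a": params.b[:, None] * (phi.T @ g1)[None, :],
        "c": g2 @ s2,
        "d": params.c[:, None] * (phi.T @ g2)[None, :],
    }
    return loss, grads


def fit(
    train: pd.DataFrame | np.ndarray,
    labels: np.ndarray | None = None,
    config: DCQMFFConfig | None = None,
) -> tuple[DCQMFFParams, list[float]]:
    """Train on a normalized cohort table (or raw (n, 11) matrix + labels).

    Labels: 1 = death, 0 = survival (from ``survived_28d`` when a cohort
    table is given).  Returns the fitted params and the per-epoch training
    loss trace.  Deterministic under the config seed.
    """
    if config is None:
        config = DCQMFFConfig()
    if isinstance(train, pd.DataFrame):
        x = train[list(FEATURES_11)].to_numpy(dtype=float)
        t_death = 1.0 - train["survived_28d"].to_numpy(dtype=float)
    else:
        x = np.asarray(train, dtype=float)
        if labels is None:
            raise ValueError("labels required with a raw feature matrix")
        t_death = np.asarray(labels, dtype=float)
    classes = np.unique(t_death)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    phi = quad_features(x)
    n = phi.shape[0]
    rng = np.random.default_rng(config.seed)
    params = DCQMFFParams.init_random(config.L, seed=int(rng.integers(2**31)))

    opt_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = loss_and_gradients(params, phi[idx], t_death[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training diverged (non-finite loss); lower the learning rate"
                )
            epoch_loss += loss * idx.size
            step += 1
            for name in ("b", "a", "c", "d"):
                g = grads[name]
                w = getattr(params, name)
                if config.optimizer == "sgd":
                    w -= config.learning_rate * g
                else:
                    m, v = opt_state.get(name, (np.zeros_like(w), np.zeros_like(w)))
                    m = beta1 * m + (1 - beta1) * g
                    v = beta2 * v + (1 - beta2) * g * g
                    opt_state[name] = (m, v)
                    mhat = m / (1 - beta1**step)
                    vhat = v / (1 - beta2**step)
                    w -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        trace.append(epoch_loss / n)
        if config.early_stop_patience is not None:
            if trace[-1] < best - 1e-6:
                best, stale = trace[-1], 0
            else:
                stale += 1
                if stale > config.early_stop_patience:
                    break
    return params, trace


def predict(
    params: DCQMFFParams, table: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Per-patient (p_survive, p_death, predicted death label).

    Label = death iff p_death > 0.5; an exact tie predicts survival (the
    majority class).
    """
    if isinstance(table, pd.DataFrame):
        x = table[list(FEATURES_11)].to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
    p = forward(params, x)
    return pd.DataFrame(
        {
            "p_survive": p[:, 0],
            "p_death": p[:, 1],
            "pred_death": (p[:, 1] > 0.5).astype(int),
        }
    )
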