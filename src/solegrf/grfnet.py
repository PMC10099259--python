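"""Seq2seq LSTM estimator: 4 load-cell channels -> 3-axis GRF.

The estimator maps a stance-phase input sequence (heel, 1st metatarsal,
5th metatarsal forces and their sum) to the ground-reaction-force
sequence of the same length (vertical, AP, ML), one output vector per
time step. The architecture is a stack of three LSTM layers (widths
200, 50, 200), each followed by a matching-width linear
fully-connected layer, with a final 3-unit linear regression head.
Training uses Adam on a masked mean-squared error computed on
z-score-normalized channels (statistics fitted on the training split
only), minibatches of 32 padded to the batch maximum.

Everything -- forward pass, backpropagation through time, Adam -- is
implemented here in numpy: the model is small enough (~0.5 M
parameters) that CPU matrix products train it in minutes, and the
explicit implementation keeps runs bit-reproducible from a seed.

Shapes: sequences are handled internally as (batch, time, channels)
float32 arrays; the public API takes and returns channels-first
(4, T) / (3, T) arrays in newtons, matching
:class:`solegrf.preprocess.StanceSegment`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import StanceSegment

__all__ = [
    "ModelConfig",
    "ChannelScaler",
    "GRFEstimator",
    "TrainedEstimator",
    "build_estimator",
    "train_estimator",
    "estimate_grf",
    "save_estimator",
    "load_estimator",
]

N_INPUT_CHANNELS = 4
N_OUTPUT_CHANNELS = 3

#: Checkpoint schema version; bump on any layout change.
CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training recipe.

    Defaults follow the published recipe: LSTM widths 200/50/200, Adam
    with learning rate 0.01, minibatch 32, 1000 epochs. ``epochs`` is
    routinely lowered for desk-scale experiments. ``grad_clip`` is the
    global gradient-norm ceiling (a numerical safeguard at this
    learning rate); ``selection`` picks which checkpoint the returned
    model carries.
    """

    lstm_widths: tuple[int, ...] = (200, 50, 200)
    epochs: int = 1000
    learning_rate: float = 0.01
    batch_size: int = 32
    optimizer: str = "adam"
    seed: int = 0
    selection: str = "best_validation"
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lstm_widths", tuple(int(w) for w in self.lstm_widths))
        if any(w < 1 for w in self.lstm_widths):
            raise ValueError("all LSTM widths must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the 'adam' optimizer is supported")
        if self.selection not in ("best_validation", "last_epoch"):
            raise ValueError(f"unknown selection {self.selection!r}")


@dataclass(frozen=True)
class ChannelScaler:
    """Per-channel z-score statistics, fitted on the training split.

    Normalization puts the vertical channel (~700 N) and the ML channel
    (~30 N) on comparable scales so the MSE loss does not ignore the
    small axes. The scaler travels with the trained model and is
    inverted at inference.
    """

    input_mean: np.ndarray
    input_sd: np.ndarray
    target_mean: np.ndarray
    target_sd: np.ndarray

    def __post_init__(self) -> None:
        for name in ("input_mean", "input_sd", "target_mean", "target_sd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.input_mean.shape != (N_INPUT_CHANNELS,) or self.input_sd.shape != (N_INPUT_CHANNELS,):
            raise ValueError("input statistics must have 4 channels")
        if self.target_mean.shape != (N_OUTPUT_CHANNELS,) or self.target_sd.shape != (N_OUTPUT_CHANNELS,):
            raise ValueError("target statistics must have 3 channels")
        if np.any(self.input_sd <= 0) or np.any(self.target_sd <= 0):
            raise ValueError("channel standard deviations must be positive")

    @classmethod
    def fit(cls, segments: Sequence[StanceSegment]) -> "ChannelScaler":
        xs = np.concatenate([s.inputs for s in segments], axis=1)
        ys = np.concatenate([s.targets for s in segments], axis=1)
        return cls(
            input_mean=xs.mean(axis=1),
            input_sd=xs.std(axis=1, ddof=0),
            target_mean=ys.mean(axis=1),
            target_sd=ys.std(axis=1, ddof=0),
        )

    def normalize_inputs(self, x: np.ndarray) -> np.ndarray:
        return (x - self.input_mean[:, None]) / self.input_sd[:, None]

    def normalize_targets(self, y: np.ndarray) -> np.ndarray:
        return (y - self.target_mean[:, None]) / self.target_sd[:, None]

    def denormalize_targets(self, y: np.ndarray) -> np.ndarray:
        return y * self.target_sd[:, None] + self.target_mean[:, None]


# ---------------------------------------------------------------------------
# Parameter initialization and the forward/backward passes.
#
# Parameters live in a flat dict of float32 arrays:
#   l{i}.W  (in_dim, 4H)   input-to-gate weights, gate order (i, f, g, o)
#   l{i}.U  (H, 4H)        recurrent weights
#   l{i}.b  (4H,)          gate biases (forget-gate slice initialized to 1)
#   l{i}.fcW (H, H), l{i}.fcb (H,)   per-layer linear FC
#   head.W (H_last, 3), head.b (3,)  regression head
# ---------------------------------------------------------------------------


def _init_params(widths: Sequence[int], seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    in_dim = N_INPUT_CHANNELS
    for i, h in enumerate(widths):
        k = 1.0 / np.sqrt(h)
        params[f"l{i}.W"] = rng.uniform(-k, k, (in_dim, 4 * h)).astype(np.float32)
        params[f"l{i}.U"] = rng.uniform(-k, k, (h, 4 * h)).astype(np.float32)
        b = rng.uniform(-k, k, 4 * h).astype(np.float32)
        b[h : 2 * h] = 1.0  # forget-gate bias: remember by default
        params[f"l{i}.b"] = b
        params[f"l{i}.fcW"] = rng.uniform(-k, k, (h, h)).astype(np.float32)
        params[f"l{i}.fcb"] = rng.uniform(-k, k, h).astype(np.float32)
        in_dim = h
    k = 1.0 / np.sqrt(in_dim)
    params["head.W"] = rng.uniform(-k, k, (in_dim, N_OUTPUT_CHANNELS)).astype(np.float32)
    params["head.b"] = rng.uniform(-k, k, N_OUTPUT_CHANNELS).astype(np.float32)
    return params


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_forward(x: np.ndarray, W: np.ndarray, U: np.ndarray, b: np.ndarray):
    """One LSTM layer over a (B, T, in) batch; returns h and a cache."""
    B, T, _ = x.shape
    H = U.shape[0]
    xp = x @ W + b  # (B, T, 4H)
    h = np.zeros((B, T, H), dtype=np.float32)
    gates = np.empty((B, T, 4 * H), dtype=np.float32)
    c_seq = np.empty((B, T, H), dtype=np.float32)
    tanh_c = np.empty((B, T, H), dtype=np.float32)
    h_t = np.zeros((B, H), dtype=np.float32)
    c_t = np.zeros((B, H), dtype=np.float32)
    for t in range(T):
        a = xp[:, t] + h_t @ U
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c_t = f * c_t + i * g
        tc = np.tanh(c_t)
        h_t = o * tc
        gates[:, t, :H] = i
        gates[:, t, H : 2 * H] = f
        gates[:, t, 2 * H : 3 * H] = g
        gates[:, t, 3 * H :] = o
        c_seq[:, t] = c_t
        tanh_c[:, t] = tc
        h[:, t] = h_t
    cache = (x, gates, c_seq, tanh_c, h)
    return h, cache


def _lstm_backward(dh_out: np.ndarray, cache, W: np.ndarray, U: np.ndarray):
    """BPTT for one LSTM layer; returns (dx, dW, dU, db)."""
    x, gates, c_seq, tanh_c, h = cache
    B, T, H = h.shape
    da_all = np.empty((B, T, 4 * H), dtype=np.float32)
    dh_next = np.zeros((B, H), dtype=np.float32)
    dc_next = np.zeros((B, H), dtype=np.float32)
    Ut = U.T
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H : 2 * H]
        g = gates[:, t, 2 * H : 3 * H]
        o = gates[:, t, 3 * H :]
        tc = tanh_c[:, t]
        c_prev = c_seq[:, t - 1] if t > 0 else np.zeros((B, H), dtype=np.float32)
        dh = dh_out[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        da = da_all[:, t]
        da[:, :H] = di * i * (1.0 - i)
        da[:, H : 2 * H] = df * f * (1.0 - f)
        da[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
        da[:, 3 * H :] = do * o * (1.0 - o)
        dh_next = da @ Ut
    flat_da = da_all.reshape(B * T, 4 * H)
    dW = x.reshape(B * T, -1).T @ flat_da
    # recurrent grad pairs h_{t-1} with a_t
    h_prev = np.concatenate(
        [np.zeros((B, 1, H), dtype=np.float32), h[:, : T - 1]], axis=1
    )
    dU = h_prev.reshape(B * T, H).T @ flat_da
    db = flat_da.sum(axis=0)
    dx = flat_da.reshape(B, T, 4 * H) @ W.T
    return dx, dW, dU, db


def _forward(params: dict[str, np.ndarray], widths: Sequence[int], x: np.ndarray, caches=None):
    """Full network forward on a (B, T, 4) batch -> (B, T, 3).

    When ``caches`` is a list it is filled with per-layer caches for the
    backward pass.
    """
    out = x
    for i in range(len(widths)):
        h, cache = _lstm_forward(out, params[f"l{i}.W"], params[f"l{i}.U"], params[f"l{i}.b"])
        out = h @ params[f"l{i}.fcW"] + params[f"l{i}.fcb"]
        if caches is not None:
            caches.append((cache, h))
    y = out @ params["head.W"] + params["head.b"]
    if caches is not None:
        caches.append(out)
    return y


def _backward(
    params: dict[str, np.ndarray],
    widths: Sequence[int],
    caches,
    dy: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of the loss w.r.t. every parameter; mirrors `_forward`."""
    grads: dict[str, np.ndarray] = {}
    head_in = caches[-1]
    B, T, _ = dy.shape
    flat_dy = dy.reshape(B * T, -1)
    grads["head.W"] = head_in.reshape(B * T, -1).T @ flat_dy
    grads["head.b"] = flat_dy.sum(axis=0)
    d = (dy @ params["head.W"].T).astype(np.float32)
    for i in range(len(widths) - 1, -1, -1):
        cache, h = caches[i]
        flat_d = d.reshape(B * T, -1)
        grads[f"l{i}.fcW"] = h.reshape(B * T, -1).T @ flat_d
        grads[f"l{i}.fcb"] = flat_d.sum(axis=0)
        dh = (d @ params[f"l{i}.fcW"].T).astype(np.float32)
        dx, dW, dU, db = _lstm_backward(dh, cache, params[f"l{i}.W"], params[f"l{i}.U"])
        grads[f"l{i}.W"] = dW
        grads[f"l{i}.U"] = dU
        grads[f"l{i}.b"] = db
        d = dx
    return grads


class _Adam:
    """Adam with bias correction and global-norm gradient clipping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, clip: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.clip, self.beta1, self.beta2, self.eps = lr, clip, beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        if self.clip > 0:
            total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
            if total > self.clip:
                scale = self.clip / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k].astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


@dataclass
class GRFEstimator:
    """An untrained (or in-training) network: parameters + config."""

    config: ModelConfig
    params: dict[str, np.ndarray]

    def predict_normalized(self, x: np.ndarray) -> np.ndarray:
        """(B, T, 4) normalized inputs -> (B, T, 3) normalized outputs."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[2] != N_INPUT_CHANNELS:
            raise ValueError(f"expected a (B, T, {N_INPUT_CHANNELS}) input, got {x.shape}")
        return _forward(self.params, self.config.lstm_widths, x)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


@dataclass
class TrainedEstimator:
    """A trained network with its scaler and training history."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    scaler: ChannelScaler
    history: dict[str, list[float]]

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        """(4, T) inputs in newtons -> (3, T) GRF estimate in newtons."""
        return estimate_grf(self, inputs)


def build_estimator(config: ModelConfig) -> GRFEstimator:
    """Seed-deterministic parameter initialization of the network."""
    return GRFEstimator(config=config, params=_init_params(config.lstm_widths, config.seed))


def _segments_to_batch(segments: Sequence[StanceSegment], scaler: ChannelScaler):
    """Normalize, pad to the longest segment, build the loss mask."""
    xs = [scaler.normalize_inputs(s.inputs).T.astype(np.float32) for s in segments]
    ys = [scaler.normalize_targets(s.targets).T.astype(np.float32) for s in segments]
    T = max(x.shape[0] for x in xs)
    B = len(xs)
    X = np.zeros((B, T, N_INPUT_CHANNELS), dtype=np.float32)
    Y = np.zeros((B, T, N_OUTPUT_CHANNELS), dtype=np.float32)
    M = np.zeros((B, T, 1), dtype=np.float32)
    for b, (x, y) in enumerate(zip(xs, ys)):
        X[b, : x.shape[0]] = x
        Y[b, : y.shape[0]] = y
        M[b, : x.shape[0]] = 1.0
    return X, Y, M


def _masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    denom = float(mask.sum()) * N_OUTPUT_CHANNELS
    return float(np.sum(mask * (pred - target) ** 2) / denom)


def train_estimator(
    estimator: GRFEstimator,
    train: Sequence[StanceSegment],
    val: Sequence[StanceSegment],
    config: ModelConfig | None = None,
) -> TrainedEstimator:
    """Train with Adam on masked, normalized MSE; subject-disjoint splits.

    Refuses to run if any subject appears in both the training and
    validation splits -- subject independence is the central validation
    principle here. Returns the checkpoint selected by
    ``config.selection`` together with the full per-epoch loss history.
    """
    config = config or estimator.config
    if not train:
        raise ValueError("training split is empty")
    overlap = {s.subject_id for s in train} & {s.subject_id for s in val}
    if overlap:
        raise ValueError(
            f"subjects {sorted(overlap)} appear in both training and validation splits"
        )

    scaler = ChannelScaler.fit(train)
    Xv = Yv = Mv = None
    if val:
        Xv, Yv, Mv = _segments_to_batch(val, scaler)

    params = estimator.copy_params()
    opt = _Adam(params, config.learning_rate, config.grad_clip)
    rng = np.random.default_rng(config.seed + 1)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_params = {k: v.copy() for k, v in params.items()}
    best_val = np.inf

    n = len(train)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_weight = 0.0
        for start in range(0, n, config.batch_size):
            batch = [train[i] for i in order[start : start + config.batch_size]]
            X, Y, M = _segments_to_batch(batch, scaler)
            caches: list = []
            pred = _forward(params, config.lstm_widths, X, caches)
            denom = float(M.sum()) * N_OUTPUT_CHANNELS
            diff = (pred - Y) * M
            loss = float(np.sum(diff**2) / denom)
            dy = (2.0 / denom) * diff
            grads = _backward(params, config.lstm_widths, caches, dy.astype(np.float32))
            opt.step(params, grads)
            epoch_loss += loss * denom
            epoch_weight += denom
        history["train_loss"].append(epoch_loss / epoch_weight)

        if val:
            val_pred = _forward(params, config.lstm_widths, Xv)
            val_loss = _masked_mse(val_pred, Yv, Mv)
            history["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}

    if config.selection == "best_validation" and val and config.epochs > 0:
        final = best_params
    else:
        final = params
    return TrainedEstimator(config=config, params=final, scaler=scaler, history=history)


def estimate_grf(model: TrainedEstimator, inputs: np.ndarray) -> np.ndarray:
    """Estimate the 3-axis GRF (N) for one (4, T) input sequence (N)."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[0] != N_INPUT_CHANNELS:
        raise ValueError(f"expected a ({N_INPUT_CHANNELS}, T) input, got {inputs.shape}")
    if not np.all(np.isfinite(inputs)):
        raise ValueError("inputs must be finite")
    x = model.scaler.normalize_inputs(inputs).T.astype(np.float32)[None]
    y = _forward(model.params, model.config.lstm_widths, x)[0]  # (T, 3)
    return model.scaler.denormalize_targets(y.T.astype(np.float64))


def save_estimator(model: TrainedEstimator, path) -> None:
    """Serialize parameters, scaler, config and history to one .npz."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": dataclasses.asdict(model.config),
        "param_keys": sorted(model.params),
    }
    arrays = {f"param::{k}": v for k, v in model.params.items()}
    arrays.update(
        scaler_input_mean=model.scaler.input_mean,
        scaler_input_sd=model.scaler.input_sd,
        scaler_target_mean=model.scaler.target_mean,
        scaler_target_sd=model.scaler.target_sd,
        history_train=np.asarray(model.history.get("train_loss", []), dtype=np.float64),
        history_val=np.asarray(model.history.get("val_loss", []), dtype=np.float64),
        meta_json=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )
    np.savez(path, **arrays)


def load_estimator(path) -> TrainedEstimator:
    """Inverse of :func:`save_estimator`; predictions are bit-identical."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        cfg = meta["config"]
        cfg["lstm_widths"] = tuple(cfg["lstm_widths"])
        config = ModelConfig(**cfg)
        params = {k: data[f"param::{k}"] for k in meta["param_keys"]}
        scaler = ChannelScaler(
            input_mean=data["scaler_input_mean"],
            input_sd=data["scaler_input_sd"],
            target_mean=data["scaler_target_mean"],
            target_sd=data["scaler_target_sd"],
        )
        history = {
            "train_loss": data["history_train"].tolist(),
            "val_loss": data["history_val"].tolist(),
        }
    return TrainedEstimator(config=config, params=params, scaler=scaler, history=history)
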