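"""Recurrent forecasters and baselines for activeness prediction.

Four recurrent layouts are provided, all built on a single GRU layer:

* ``UNI_MO`` / ``MULTI_MO`` — many-to-one: the GRU consumes the whole input
  window and the final hidden state is mapped, through dropout and a ReLU
  dense layer, to the entire output window in one shot. The output length is
  free of the input length.
* ``UNI_MM`` / ``MULTI_MM`` — many-to-many: the GRU emits a prediction at
  every time step through a shared linear head, so the output window has the
  same length as the input window.

Univariate models see one biometric channel; multivariate models see all
three at once. Two baselines complete the lineup: a feed-forward ``DNN``
(flattened window -> dense 52 -> dense 26 -> linear, ReLU activations) and an
``OLS`` linear map from the flattened input window to the flattened output
window, solved in closed form.

Everything is implemented directly in numpy — forward pass,
backpropagation-through-time, Adam, inverted dropout and early stopping on a
held-out validation split — so training is exactly reproducible from a seed.

GRU cell (update gate z, reset gate r, candidate state):

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
    g_t = tanh(x_t Wh + (r_t * h_{t-1}) Uh + bh)
    h_t = (1 - z_t) * h_{t-1} + z_t * g_t
"""

from __future__ import annotations

import copy
import enum
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocessing import WindowedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Architecture",
    "ModelConfig",
    "ModelHandle",
    "build_model",
    "train",
    "predict_window",
    "num_parameters",
    "save_model",
    "load_model",
]


class Architecture(str, enum.Enum):
    UNI_MO = "uni_mo"
    UNI_MM = "uni_mm"
    MULTI_MO = "multi_mo"
    MULTI_MM = "multi_mm"
    DNN_BASELINE = "dnn_baseline"
    OLS_BASELINE = "ols_baseline"


RECURRENT = {
    Architecture.UNI_MO,
    Architecture.UNI_MM,
    Architecture.MULTI_MO,
    Architecture.MULTI_MM,
}
MANY_TO_MANY = {Architecture.UNI_MM, Architecture.MULTI_MM}
UNIVARIATE = {Architecture.UNI_MO, Architecture.UNI_MM}
MULTIVARIATE = {Architecture.MULTI_MO, Architecture.MULTI_MM}


@dataclass
class ModelConfig:
    architecture: Architecture
    input_len: int = 15
    output_len: int = 15
    channels_in: int = 1
    channels_out: int = 1
    hidden_units: int = 52
    dense_units: int | None = None  # MO head; defaults to hidden_units
    dnn_hidden: tuple = (52, 26)
    dropout: float = 0.2
    learning_rate: float = 1e-3
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    batch_size: int = 128
    max_epochs: int = 200
    early_stopping_patience: int = 5
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.architecture = Architecture(self.architecture)
        if self.dense_units is None:
            self.dense_units = self.hidden_units
        a = self.architecture
        if a in UNIVARIATE and (self.channels_in != 1 or self.channels_out != 1):
            raise ValueError("univariate architectures require one channel in and out")
        if a in MULTIVARIATE and (self.channels_in != 3 or self.channels_out != 3):
            raise ValueError("multivariate architectures require three channels in and out")
        if a in MANY_TO_MANY and self.output_len != self.input_len:
            raise ValueError(
                "many-to-many architectures emit one output per input step; "
                "output_len must equal input_len"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.input_len < 1 or self.output_len < 1:
            raise ValueError("window lengths must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["architecture"] = self.architecture.value
        d["dnn_hidden"] = list(self.dnn_hidden)
        d["adam_betas"] = list(self.adam_betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["dnn_hidden"] = tuple(d.get("dnn_hidden", (52, 26)))
        d["adam_betas"] = tuple(d.get("adam_betas", (0.9, 0.999)))
        return cls(**d)


@dataclass
class ModelHandle:
    """A (possibly trained) forecaster: config + learned parameters."""

    config: ModelConfig
    params: dict = field(default_factory=dict)
    trained: bool = False
    training_history: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_params(config: ModelConfig, rng: np.random.Generator) -> dict:
    a = config.architecture
    C, H = config.channels_in, config.hidden_units
    m_out = config.output_len * config.channels_out
    p: dict[str, np.ndarray] = {}
    if a in RECURRENT:
        for gate in ("z", "r", "h"):
            p[f"W{gate}"] = _glorot(rng, C, H)
            p[f"U{gate}"] = _glorot(rng, H, H)
            p[f"b{gate}"] = np.zeros(H)
        if a in MANY_TO_MANY:
            p["V"] = _glorot(rng, H, config.channels_out)
            p["c"] = np.zeros(config.channels_out)
        else:
            D = config.dense_units
            p["W1"] = _glorot(rng, H, D)
            p["b1"] = np.zeros(D)
            p["W2"] = _glorot(rng, D, m_out)
            p["b2"] = np.zeros(m_out)
    elif a is Architecture.DNN_BASELINE:
        sizes = (config.input_len * C,) + tuple(config.dnn_hidden) + (m_out,)
        for i in range(len(sizes) - 1):
            p[f"W{i}"] = _glorot(rng, sizes[i], sizes[i + 1])
            p[f"b{i}"] = np.zeros(sizes[i + 1])
    elif a is Architecture.OLS_BASELINE:
        p["coef"] = np.zeros((config.input_len * C + 1, m_out))
    return p


def build_model(config: ModelConfig) -> ModelHandle:
    """Instantiate an untrained model with seeded initial parameters."""
    rng = np.random.default_rng(config.seed)
    return ModelHandle(config=config, params=_init_params(config, rng))


# ---------------------------------------------------------------------------
# GRU forward / backward
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _gru_forward(X: np.ndarray, p: dict) -> tuple[np.ndarray, list]:
    """X: (B, T, C) -> hidden states (B, T, H) and per-step caches."""
    B, T, _ = X.shape
    H = p["bz"].shape[0]
    h = np.zeros((B, H))
    states = np.empty((B, T, H))
    caches = []
    for t in range(T):
        x = X[:, t]
        z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
        r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
        g = np.tanh(x @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
        h_new = (1.0 - z) * h + z * g
        caches.append((x, h, z, r, g))
        states[:, t] = h_new
        h = h_new
    return states, caches


def _gru_backward(dstates: np.ndarray, caches: list, p: dict) -> dict:
    """Backprop-through-time; dstates: (B, T, H) gradients wrt each state."""
    grads = {k: np.zeros_like(p[k]) for k in ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wh", "Uh", "bh")}
    T = dstates.shape[1]
    dh_next = np.zeros_like(dstates[:, 0])
    for t in range(T - 1, -1, -1):
        x, h_prev, z, r, g = caches[t]
        dh = dstates[:, t] + dh_next
        dz = dh * (g - h_prev)
        dg = dh * z
        dh_prev = dh * (1.0 - z)
        da_h = dg * (1.0 - g * g)
        grads["Wh"] += x.T @ da_h
        grads["Uh"] += (r * h_prev).T @ da_h
        grads["bh"] += da_h.sum(axis=0)
        drh = da_h @ p["Uh"].T
        dh_prev += drh * r
        dr = drh * h_prev
        da_z = dz * z * (1.0 - z)
        grads["Wz"] += x.T @ da_z
        grads["Uz"] += h_prev.T @ da_z
        grads["bz"] += da_z.sum(axis=0)
        dh_prev += da_z @ p["Uz"].T
        da_r = dr * r * (1.0 - r)
        grads["Wr"] += x.T @ da_r
        grads["Ur"] += h_prev.T @ da_r
        grads["br"] += da_r.sum(axis=0)
        dh_prev += da_r @ p["Ur"].T
        dh_next = dh_prev
    return grads


def _dropout_mask(rng, shape, rate: float) -> np.ndarray:
    return (rng.random(shape) >= rate) / (1.0 - rate)


# ---------------------------------------------------------------------------
# full model forward / backward
# ---------------------------------------------------------------------------


def _forward(
    config: ModelConfig,
    p: dict,
    X: np.ndarray,
    train_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Forward pass. Dropout is active iff ``train_rng`` is given."""
    a = config.architecture
    B = X.shape[0]
    rate = config.dropout
    dropout_on = train_rng is not None and rate > 0.0
    cache: dict = {}
    if a in RECURRENT:
        states, gru_cache = _gru_forward(X, p)
        cache["gru"] = gru_cache
        if a in MANY_TO_MANY:
            Hs = states
            if dropout_on:
                mask = _dropout_mask(train_rng, Hs.shape, rate)
                Hs = Hs * mask
                cache["mask_h"] = mask
            cache["Hs"] = Hs
            out = Hs @ p["V"] + p["c"]  # (B, T, channels_out)
        else:
            hT = states[:, -1]
            if dropout_on:
                mask = _dropout_mask(train_rng, hT.shape, rate)
                hT = hT * mask
                cache["mask_h"] = mask
            z1 = hT @ p["W1"] + p["b1"]
            a1 = np.maximum(z1, 0.0)
            if dropout_on:
                mask1 = _dropout_mask(train_rng, a1.shape, rate)
                a1 = a1 * mask1
                cache["mask_1"] = mask1
            cache.update(hT=hT, z1=z1, a1=a1)
            out = (a1 @ p["W2"] + p["b2"]).reshape(
                B, config.output_len, config.channels_out
            )
    elif a is Architecture.DNN_BASELINE:
        f = X.reshape(B, -1)
        acts = [f]
        n_hidden = len(config.dnn_hidden)
        h = f
        masks = []
        zs = []
        for i in range(n_hidden):
            z = h @ p[f"W{i}"] + p[f"b{i}"]
            h = np.maximum(z, 0.0)
            zs.append(z)
            if dropout_on:
                mask = _dropout_mask(train_rng, h.shape, rate)
                h = h * mask
                masks.append(mask)
            acts.append(h)
        out = (h @ p[f"W{n_hidden}"] + p[f"b{n_hidden}"]).reshape(
            B, config.output_len, config.channels_out
        )
        cache.update(acts=acts, zs=zs, masks=masks)
    elif a is Architecture.OLS_BASELINE:
        f = np.concatenate([X.reshape(B, -1), np.ones((B, 1))], axis=1)
        out = (f @ p["coef"]).reshape(B, config.output_len, config.channels_out)
        cache["f"] = f
    else:  # pragma: no cover
        raise ValueError(f"unknown architecture {a}")
    return out, cache


def _backward(
    config: ModelConfig, p: dict, X: np.ndarray, dout: np.ndarray, cache: dict
) -> dict:
    a = config.architecture
    B = X.shape[0]
    grads: dict[str, np.ndarray] = {}
    if a in MANY_TO_MANY:
        Hs = cache["Hs"]
        grads["V"] = np.einsum("bth,btc->hc", Hs, dout)
        grads["c"] = dout.sum(axis=(0, 1))
        dHs = dout @ p["V"].T
        if "mask_h" in cache:
            dHs = dHs * cache["mask_h"]
        grads.update(_gru_backward(dHs, cache["gru"], p))
    elif a in RECURRENT:
        dflat = dout.reshape(B, -1)
        a1, z1, hT = cache["a1"], cache["z1"], cache["hT"]
        grads["W2"] = a1.T @ dflat
        grads["b2"] = dflat.sum(axis=0)
        da1 = dflat @ p["W2"].T
        if "mask_1" in cache:
            da1 = da1 * cache["mask_1"]
        dz1 = da1 * (z1 > 0.0)
        grads["W1"] = hT.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dhT = dz1 @ p["W1"].T
        if "mask_h" in cache:
            dhT = dhT * cache["mask_h"]
        dstates = np.zeros((B, config.input_len, config.hidden_units))
        dstates[:, -1] = dhT
        grads.update(_gru_backward(dstates, cache["gru"], p))
    elif a is Architecture.DNN_BASELINE:
        dflat = dout.reshape(B, -1)
        acts, zs, masks = cache["acts"], cache["zs"], cache["masks"]
        n_hidden = len(config.dnn_hidden)
        grads[f"W{n_hidden}"] = acts[-1].T @ dflat
        grads[f"b{n_hidden}"] = dflat.sum(axis=0)
        dh = dflat @ p[f"W{n_hidden}"].T
        for i in range(n_hidden - 1, -1, -1):
            if masks:
                dh = dh * masks[i]
            dz = dh * (zs[i] > 0.0)
            grads[f"W{i}"] = acts[i].T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ p[f"W{i}"].T
    else:
        raise ValueError("OLS baseline has no gradient training path")
    return grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: dict, lr: float, betas: tuple, eps: float):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / (1.0 - self.b1**self.t)
            vhat = self.v[k] / (1.0 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _mse_loss(out: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    diff = out - y
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size


def _check_shapes(config: ModelConfig, data: WindowedDataset) -> None:
    if data.n_samples == 0:
        raise ValueError("empty dataset")
    if data.inputs.shape[1:] != (config.input_len, config.channels_in):
        raise ValueError("input window shape does not match the model config")
    if data.targets.shape[1:] != (config.output_len, config.channels_out):
        raise ValueError("target window shape does not match the model config")


def _split_validation(
    data: WindowedDataset, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = data.n_samples
    n_val = max(1, int(round(n * fraction)))
    if n_val >= n:
        raise ValueError("not enough samples to hold out a validation set")
    perm = rng.permutation(n)
    return perm[n_val:], perm[:n_val]


def train(
    handle: ModelHandle,
    train_data: WindowedDataset,
    val_data: WindowedDataset | None = None,
) -> ModelHandle:
    """Fit the model; returns the same handle, trained.

    Gradient models minimize MSE with Adam; dropout is active during
    training only; training stops when the validation loss has not improved
    for ``early_stopping_patience`` consecutive epochs (best parameters are
    restored) or at ``max_epochs``. When no validation set is supplied, a
    random ``val_fraction`` of the training windows is held out, chosen by
    the model seed. The OLS baseline is solved in closed form and ignores
    the epoch settings.
    """
    config = handle.config
    _check_shapes(config, train_data)

    if config.architecture is Architecture.OLS_BASELINE:
        B = train_data.n_samples
        f = np.concatenate(
            [train_data.inputs.reshape(B, -1), np.ones((B, 1))], axis=1
        )
        y = train_data.targets.reshape(B, -1)
        coef, *_ = np.linalg.lstsq(f, y, rcond=None)
        handle.params["coef"] = coef
        fit_mse = float(np.mean((f @ coef - y) ** 2))
        handle.training_history = [
            {"epoch": 0, "train_loss": fit_mse, "val_loss": fit_mse}
        ]
        handle.trained = True
        return handle

    rng = np.random.default_rng(config.seed)
    p = handle.params
    if val_data is None:
        tr_idx, va_idx = _split_validation(train_data, config.val_fraction, rng)
        X_tr, y_tr = train_data.inputs[tr_idx], train_data.targets[tr_idx]
        X_va, y_va = train_data.inputs[va_idx], train_data.targets[va_idx]
    else:
        _check_shapes(config, val_data)
        X_tr, y_tr = train_data.inputs, train_data.targets
        X_va, y_va = val_data.inputs, val_data.targets

    opt = _Adam(p, config.learning_rate, config.adam_betas, config.adam_eps)
    best_val = np.inf
    best_params = copy.deepcopy(p)
    since_best = 0
    history = []
    n = X_tr.shape[0]
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for b0 in range(0, n, config.batch_size):
            idx = perm[b0 : b0 + config.batch_size]
            out, cache = _forward(config, p, X_tr[idx], train_rng=rng)
            loss, dout = _mse_loss(out, y_tr[idx])
            grads = _backward(config, p, X_tr[idx], dout, cache)
            opt.step(p, grads)
            epoch_loss += loss
            n_batches += 1
        val_out, _ = _forward(config, p, X_va)
        val_loss, _ = _mse_loss(val_out, y_va)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = copy.deepcopy(p)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                logger.debug("early stop at epoch %d (best val %.3g)", epoch, best_val)
                break
    handle.params = best_params
    handle.training_history = history
    handle.trained = True
    return handle


def predict_window(handle: ModelHandle, input_window: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout off) on one window or a batch."""
    if not handle.trained:
        raise ValueError("model not trained")
    config = handle.config
    X = np.asarray(input_window, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[1:] != (config.input_len, config.channels_in):
        raise ValueError("input window shape does not match the model config")
    out, _ = _forward(config, handle.params, X)
    return out[0] if single else out


def num_parameters(handle: ModelHandle) -> int:
    return int(sum(v.size for v in handle.params.values()))


def save_model(handle: ModelHandle, path: str) -> None:
    """Self-describing archive: npz of parameters + embedded config JSON."""
    meta = json.dumps(
        {
            "config": handle.config.to_dict(),
            "trained": handle.trained,
            "training_history": handle.training_history,
        }
    )
    np.savez(path, __meta__=np.array(meta), **handle.params)


def load_model(path: str) -> ModelHandle:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    return ModelHandle(
        config=ModelConfig.from_dict(meta["config"]),
        params=params,
        trained=meta["trained"],
        training_history=meta["training_history"],
    )
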