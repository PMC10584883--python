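"""Bidirectional-LSTM sleep stager over per-epoch feature sequences.

A sequence-labeling network implemented directly in numpy: the input layer
takes the four per-epoch features (HR, RR, lambda, BMF), followed by a
stack of bidirectional LSTM layers (dropout after each), a fully connected
layer with six output neurons — one per class N1, N2, N3, REM, WK, LV —
and a softmax.  Training minimises the categorical cross-entropy

    CEL = -(1/N) sum_i sum_c 1[y_i = c] ln p_hat_ic

with Adam, a learning rate dropped to one-hundredth every 50 training
epochs, global L2-norm gradient clipping, L2 weight regularisation, and
early stopping on validation loss.  All training sequences form a single
mini-batch zero-padded to the longest sequence (sorted by length first),
with padded positions masked out of the loss.

Everything is deterministic for a fixed seed; prediction is the per-epoch
argmax of the softmax with ties broken toward the lower class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram

#: fixed output-class ordering of the network
CLASS_ORDER: tuple[str, ...] = ("N1", "N2", "N3", "REM", "WK", "LV")
_CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}

N_FEATURES = 4


@dataclass
class StagerConfig:
    """Hyperparameters; the defaults are the selected full-scale values."""

    n_bilstm_layers: int = 3
    hidden_units: int = 128
    dropout_rate: float = 0.2
    n_classes: int = 6
    initial_lr: float = 1e-2
    lr_drop_factor: float = 0.01
    lr_drop_period: int = 50
    l2_regularization: float = 0.1
    grad_clip_l2: float = 2.0
    max_epochs: int = 5000
    early_stop_patience: int = 50
    min_improvement: float = 1e-5
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_bilstm_layers < 1 or self.hidden_units < 1:
            raise ValueError("layer and unit counts must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes != len(CLASS_ORDER):
            raise ValueError(f"n_classes must be {len(CLASS_ORDER)} for the "
                             f"class set {CLASS_ORDER}")

    @classmethod
    def fast(cls, **overrides) -> "StagerConfig":
        """Desk-scale profile: one biLSTM layer of 32 units, shorter cap.

        Intended for small synthetic cohorts and continuous testing; the
        default constructor keeps the full-scale selected values.
        """
        base = dict(n_bilstm_layers=1, hidden_units=32, max_epochs=200)
        base.update(overrides)
        return cls(**base)


def encode_labels(labels) -> np.ndarray:
    return np.array([_CLASS_INDEX[str(l).upper()] for l in labels], dtype=int)


# -------------------------------------------------------------------------
# parameter container / initialisation
# -------------------------------------------------------------------------

def _init_params(config: StagerConfig) -> dict[str, np.ndarray]:
    """Seeded uniform fan-in initialisation; forget-gate biases start at 1."""
    rng = np.random.default_rng(config.seed)
    H = config.hidden_units
    params: dict[str, np.ndarray] = {}

    def uni(shape, fan_in):
        s = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-s, s, size=shape)

    d_in = N_FEATURES
    for layer in range(config.n_bilstm_layers):
        for d in ("f", "b"):
            params[f"Wx{layer}{d}"] = uni((d_in, 4 * H), d_in)
            params[f"Wh{layer}{d}"] = uni((H, 4 * H), H)
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget gate
            params[f"b{layer}{d}"] = b
        d_in = 2 * H
    params["Wfc"] = uni((d_in, config.n_classes), d_in)
    params["bfc"] = np.zeros(config.n_classes)
    return params


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _reverse_within_lengths(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its true length; end padding stays put."""
    out = np.zeros_like(X)
    for b, L in enumerate(lengths):
        out[b, :L] = X[b, :L][::-1]
        out[b, L:] = X[b, L:]
    return out


def _lstm_forward(X, Wx, Wh, b):
    """Unidirectional LSTM over X (B,T,Din); returns hidden states and the
    per-step cache needed for backpropagation."""
    B, T, _ = X.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.zeros((B, T, H))
    cache = {k: np.zeros((B, T, H)) for k in ("i", "f", "g", "o", "c", "tc", "hprev", "cprev")}
    XW = X @ Wx  # precompute input projections for all steps
    for t in range(T):
        z = XW[:, t] + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        cache["hprev"][:, t] = h
        cache["cprev"][:, t] = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        Hs[:, t] = h
        cache["i"][:, t], cache["f"][:, t] = i, f
        cache["g"][:, t], cache["o"][:, t] = g, o
        cache["c"][:, t], cache["tc"][:, t] = c, tc
    return Hs, cache


def _lstm_backward(dH, X, Wx, Wh, cache):
    """Gradient of an LSTM pass; returns (dX, dWx, dWh, db)."""
    B, T, H = dH.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o = (cache[k][:, t] for k in ("i", "f", "g", "o"))
        tc = cache["tc"][:, t]
        cprev = cache["cprev"][:, t]
        hprev = cache["hprev"][:, t]
        dh = dH[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1 - tc * tc) + dc_next
        di = dc * g
        df = dc * cprev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dWx += X[:, t].T @ dz
        dWh += hprev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dX, dWx, dWh, db


def _forward(params, config, X, lengths, dropout_rng=None):
    """Network forward pass.  Returns (probs, caches); dropout is active
    only when a generator is supplied (training mode)."""
    B, T, _ = X.shape
    caches = []
    inp = X
    for layer in range(config.n_bilstm_layers):
        Hf, cf = _lstm_forward(inp, params[f"Wx{layer}f"], params[f"Wh{layer}f"], params[f"b{layer}f"])
        Xr = _reverse_within_lengths(inp, lengths)
        Hb_r, cb = _lstm_forward(Xr, params[f"Wx{layer}b"], params[f"Wh{layer}b"], params[f"b{layer}b"])
        Hb = _reverse_within_lengths(Hb_r, lengths)
        out = np.concatenate([Hf, Hb], axis=2)
        if dropout_rng is not None and config.dropout_rate > 0:
            mask = (dropout_rng.random(out.shape) >= config.dropout_rate) / (1 - config.dropout_rate)
            out = out * mask
        else:
            mask = None
        caches.append({"inp": inp, "Xr": Xr, "cf": cf, "cb": cb, "Hb_r": Hb_r,
                       "mask": mask, "layer_out": out})
        inp = out
    logits = inp @ params["Wfc"] + params["bfc"]
    logits -= logits.max(axis=2, keepdims=True)
    ex = np.exp(logits)
    probs = ex / ex.sum(axis=2, keepdims=True)
    return probs, caches


def _backward(params, config, probs, caches, X, lengths, y_onehot, valid_mask):
    """Gradient of the masked mean cross-entropy wrt every parameter."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    n_valid = valid_mask.sum()
    dlogits = (probs - y_onehot) * valid_mask[:, :, None] / n_valid
    top = caches[-1]["layer_out"]
    grads["Wfc"] = np.tensordot(top, dlogits, axes=([0, 1], [0, 1]))
    grads["bfc"] = dlogits.sum(axis=(0, 1))
    dout = dlogits @ params["Wfc"].T
    for layer in range(config.n_bilstm_layers - 1, -1, -1):
        cache = caches[layer]
        if cache["mask"] is not None:
            dout = dout * cache["mask"]
        H = config.hidden_units
        dHf = dout[:, :, :H]
        dHb = dout[:, :, H:]
        dXf, dWxf, dWhf, dbf = _lstm_backward(
            dHf, cache["inp"], params[f"Wx{layer}f"], params[f"Wh{layer}f"], cache["cf"]
        )
        dHb_r = _reverse_within_lengths(dHb, lengths)
        dXb_r, dWxb, dWhb, dbb = _lstm_backward(
            dHb_r, cache["Xr"], params[f"Wx{layer}b"], params[f"Wh{layer}b"], cache["cb"]
        )
        dXb = _reverse_within_lengths(dXb_r, lengths)
        grads[f"Wx{layer}f"], grads[f"Wh{layer}f"], grads[f"b{layer}f"] = dWxf, dWhf, dbf
        grads[f"Wx{layer}b"], grads[f"Wh{layer}b"], grads[f"b{layer}b"] = dWxb, dWhb, dbb
        dout = dXf + dXb
    return grads


# -------------------------------------------------------------------------
# public model object
# -------------------------------------------------------------------------

@dataclass
class TrainedStager:
    """Network weights + configuration (+ training history when trained)."""

    params: dict[str, np.ndarray]
    config: StagerConfig
    feature_mean: np.ndarray = field(default_factory=lambda: np.zeros(N_FEATURES))
    feature_sd: np.ndarray = field(default_factory=lambda: np.ones(N_FEATURES))
    history: pd.DataFrame | None = None
    class_order: tuple[str, ...] = CLASS_ORDER

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = dict(self.params)
        arrays["__feature_mean"] = self.feature_mean
        arrays["__feature_sd"] = self.feature_sd
        np.savez(path.with_suffix(".npz"), **arrays)
        with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(asdict(self.config), fh, indent=1)
        if self.history is not None:
            self.history.to_csv(path.with_suffix(".history.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedStager":
        path = Path(path)
        with open(path.with_suffix(".json"), encoding="utf-8") as fh:
            config = StagerConfig(**json.load(fh))
        data = np.load(path.with_suffix(".npz"))
        params = {k: data[k] for k in data.files if not k.startswith("__")}
        hist_path = path.with_suffix(".history.csv")
        history = pd.read_csv(hist_path) if hist_path.exists() else None
        return cls(params=params, config=config,
                   feature_mean=data["__feature_mean"],
                   feature_sd=data["__feature_sd"], history=history)


def build_stager(config: StagerConfig) -> TrainedStager:
    """Fresh (untrained) network with seeded initial weights."""
    return TrainedStager(params=_init_params(config), config=config)


def cross_entropy_loss(probs: np.ndarray, labels, floor: float = 1e-12) -> float:
    """Categorical cross-entropy −(1/N) Σ_i Σ_c 1[y_i=c] ln p_ic.

    ``labels`` are stage names or class indices; predicted probabilities are
    floored at 1e-12 before the logarithm.
    """
    probs = np.asarray(probs, dtype=float)
    y = labels if isinstance(labels, np.ndarray) and labels.dtype.kind == "i" \
        else encode_labels(labels)
    if len(y) != len(probs):
        raise ValueError("probabilities and labels must be aligned")
    p = np.maximum(probs[np.arange(len(y)), y], floor)
    return float(-np.mean(np.log(p)))


def _pack(features_list, labels_list):
    lengths = np.array([len(f) for f in features_list], dtype=int)
    T = int(lengths.max())
    B = len(features_list)
    X = np.zeros((B, T, N_FEATURES))
    Y = np.zeros((B, T), dtype=int)
    M = np.zeros((B, T), dtype=bool)
    for b, (f, l) in enumerate(zip(features_list, labels_list)):
        arr = np.asarray(f, dtype=float)
        X[b, :len(arr)] = arr
        Y[b, :len(arr)] = encode_labels(l)
        M[b, :len(arr)] = True
    return X, Y, M, lengths


def _eval_loss_acc(params, config, X, Y, M, lengths):
    probs, _ = _forward(params, config, X, lengths, dropout_rng=None)
    n = M.sum()
    p_true = np.maximum(probs[np.arange(X.shape[0])[:, None], np.arange(X.shape[1])[None, :], Y], 1e-12)
    loss = float(-(np.log(p_true) * M).sum() / n)
    pred = probs.argmax(axis=2)
    acc = float(((pred == Y) & M).sum() / n)
    return loss, acc


def _learning_rate(config: StagerConfig, epoch: int) -> float:
    """LR for a 1-based training epoch: dropped by ``lr_drop_factor`` every
    ``lr_drop_period`` epochs."""
    return config.initial_lr * config.lr_drop_factor ** ((epoch - 1) // config.lr_drop_period)


def train_stager(train_features, train_labels, config: StagerConfig,
                 validation) -> TrainedStager:
    """Train on a cohort of (features, labels) sequences.

    ``train_features``: list of (T_i, 4) arrays (LV-padded); ``train_labels``
    matching label sequences; ``validation``: (features_list, labels_list)
    used for the loss/accuracy stopping criterion.  Returns the weights of
    the best validation loss.
    """
    if len(train_features) == 0:
        raise ValueError("empty training set")
    if len(train_features) != len(train_labels):
        raise ValueError("features/labels cohort size mismatch")
    order = sorted(range(len(train_features)),
                   key=lambda i: (len(train_features[i]), i))
    feats = [np.asarray(train_features[i], dtype=float) for i in order]
    labs = [train_labels[i] for i in order]

    if config.standardize:
        allrows = np.concatenate(feats, axis=0)
        mu = allrows.mean(axis=0)
        sd = np.maximum(allrows.std(axis=0), 1e-8)
    else:
        mu = np.zeros(N_FEATURES)
        sd = np.ones(N_FEATURES)
    feats = [(f - mu) / sd for f in feats]
    val_feats = [(np.asarray(f, dtype=float) - mu) / sd for f in validation[0]]
    val_labs = validation[1]

    X, Y, M, lengths = _pack(feats, labs)
    Xv, Yv, Mv, lv = _pack(val_feats, val_labs)
    onehot = np.zeros(X.shape[:2] + (config.n_classes,))
    onehot[np.arange(X.shape[0])[:, None], np.arange(X.shape[1])[None, :], Y] = 1.0
    onehot *= M[:, :, None]

    params = _init_params(config)
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    drop_rng = np.random.default_rng(config.seed + 1)

    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        lr = _learning_rate(config, epoch)
        probs, caches = _forward(params, config, X, lengths, dropout_rng=drop_rng)
        n = M.sum()
        p_true = np.maximum(
            probs[np.arange(X.shape[0])[:, None], np.arange(X.shape[1])[None, :], Y], 1e-12)
        train_loss = float(-(np.log(p_true) * M).sum() / n)
        if not np.isfinite(train_loss):
            raise RuntimeError(f"training diverged: loss={train_loss} at epoch {epoch}")
        grads = _backward(params, config, probs, caches, X, lengths, onehot, M)
        if config.l2_regularization:
            for k in grads:
                if k.startswith("W"):
                    grads[k] = grads[k] + config.l2_regularization * params[k]
        gnorm = float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))
        if gnorm > config.grad_clip_l2 and gnorm > 0:
            scale = config.grad_clip_l2 / gnorm
            for k in grads:
                grads[k] = grads[k] * scale
            post_norm = config.grad_clip_l2
        else:
            post_norm = gnorm
        for k in params:
            adam_m[k] = b1 * adam_m[k] + (1 - b1) * grads[k]
            adam_v[k] = b2 * adam_v[k] + (1 - b2) * grads[k] ** 2
            mhat = adam_m[k] / (1 - b1 ** epoch)
            vhat = adam_v[k] / (1 - b2 ** epoch)
            params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)

        val_loss, val_acc = _eval_loss_acc(params, config, Xv, Yv, Mv, lv)
        rows.append((epoch, lr, post_norm, train_loss, val_loss, val_acc))
        if val_loss < best_loss - config.min_improvement:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
        elif epoch - best_epoch >= config.early_stop_patience:
            break

    history = pd.DataFrame(
        rows, columns=["epoch", "lr", "grad_norm", "train_loss", "val_loss", "val_acc"]
    )
    return TrainedStager(params=best_params, config=config,
                         feature_mean=mu, feature_sd=sd, history=history)


def predict_stages(model: TrainedStager, features) -> tuple[Hypnogram, np.ndarray]:
    """Per-epoch stage prediction for one record.

    Accepts a (T, 4) array or a feature table; returns the predicted
    hypnogram (argmax of the softmax, ties to the lower class index) and
    the (T, 6) probability matrix.
    """
    if isinstance(features, pd.DataFrame):
        from .features import feature_matrix
        arr = feature_matrix(features)
    else:
        arr = np.asarray(features, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_FEATURES:
        raise ValueError(f"expected (n_epochs, {N_FEATURES}) features, got {arr.shape}")
    arr = (arr - model.feature_mean) / model.feature_sd
    X = arr[None, :, :]
    lengths = np.array([arr.shape[0]])
    probs, _ = _forward(model.params, model.config, X, lengths, dropout_rng=None)
    probs = probs[0]
    pred = probs.argmax(axis=1)
    return Hypnogram(CLASS_ORDER[i] for i in pred), probs


def loocv(cohort_features, cohort_labels, config: StagerConfig,
          subject_ids=None):
    """Leave-one-subject-out cross-validation.

    For each subject the model is trained on the remaining subjects with
    the held-out subject serving as the stopping-criterion validation set
    (as in the original protocol), then predicts that subject.  Per-subject
    seeds are keyed by the stable subject id so results are invariant to
    cohort ordering.  Returns a list of (true Hypnogram, predicted
    Hypnogram) pairs in input order.
    """
    n = len(cohort_features)
    if n < 3:
        raise ValueError("leave-one-out needs >= 3 subjects")
    if subject_ids is None:
        subject_ids = list(range(n))
    pairs = []
    for s in range(n):
        cfg = StagerConfig(**{**asdict(config),
                              "seed": int((config.seed * 1_000_003 + subject_ids[s]) % 2**31)})
        # canonical id order makes the fold independent of cohort ordering
        idx = sorted((i for i in range(n) if i != s), key=lambda i: subject_ids[i])
        train_f = [cohort_features[i] for i in idx]
        train_l = [cohort_labels[i] for i in idx]
        model = train_stager(train_f, train_l, cfg,
                             validation=([cohort_features[s]], [cohort_labels[s]]))
        pred, _ = predict_stages(model, cohort_features[s])
        true = cohort_labels[s] if isinstance(cohort_labels[s], Hypnogram) \
            else Hypnogram(cohort_labels[s])
        pairs.append((true, pred))
    return pairs
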