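"""Gated attention-based multiple-instance learning for slide-level prediction.

The classifier operates on a bag of patch feature vectors ``h_k`` and never
sees patch-level labels.  Each patch is projected to a hidden embedding,
scored by a gated attention branch

    e_k = w^T ( tanh(V p_k) * sigmoid(U p_k) ),     a = softmax(e)

and the bag embedding ``M = sum_k a_k p_k`` is classified into
recurrence / non-recurrence.  An auxiliary instance-clustering branch
pseudo-labels the top-k attention patches with the bag's class and the
bottom-k with the complement class and trains an instance classifier on
them, encouraging attention to separate class-evidence patches from the
rest.  The total loss is ``c1 * bagCE + c2 * instanceCE``.

Training uses Adam with one optimization step per bag and early stopping on
a validation split: training ends when the validation loss has not improved
its running minimum for ``patience`` consecutive epochs, and the parameters
from the best epoch are returned.

Implemented directly in numpy (forward and backward passes are explicit);
a finite-difference gradient check in the test suite guards the backprop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .synthetic import PatchBag

__all__ = [
    "MILConfig",
    "MILModel",
    "AttentionOutput",
    "TrainHistory",
    "EarlyStopping",
    "attention_weights",
    "bag_forward",
    "normalize_attention",
    "instance_loss",
    "bag_loss_and_grads",
    "train_mil",
    "predict_wsi_score",
    "save_model",
    "load_model",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class MILConfig:
    feature_dim: int = 64
    hidden_dim: int = 128
    attention_dim: int = 64
    dropout_rate: float = 0.0
    learning_rate: float = 2e-4
    max_epochs: int = 200
    patience: int = 20
    bag_loss_weight: float = 0.7      # c1
    instance_loss_weight: float = 0.3  # c2
    instance_k: int = 8
    seed: int = 0

    def validate(self) -> None:
        if abs(self.bag_loss_weight + self.instance_loss_weight - 1.0) > 1e-9:
            raise ValueError("bag_loss_weight + instance_loss_weight must equal 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.feature_dim < 1 or self.hidden_dim < 1 or self.attention_dim < 1:
            raise ValueError("dimensions must be >= 1")


class MILModel:
    """Parameter container for the gated-attention MIL network.

    Parameters: projection (Wp, bp), gated attention (Wv, bv, Wu, bu, w, bw),
    bag classifier (Wc, bc) and instance classifier (Wi, bi).  Classifier
    weights start at zero so an untrained model outputs probability 0.5.
    """

    PARAM_NAMES = ("Wp", "bp", "Wv", "bv", "Wu", "bu", "w", "bw", "Wc", "bc", "Wi", "bi")

    def __init__(self, config: MILConfig):
        config.validate()
        self.config = config
        d, h, a = config.feature_dim, config.hidden_dim, config.attention_dim
        rng = np.random.default_rng(config.seed)

        def init(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(1.0 / fan_in)

        self.params: dict[str, np.ndarray] = {
            "Wp": init((d, h), d), "bp": np.zeros(h),
            "Wv": init((h, a), h), "bv": np.zeros(a),
            "Wu": init((h, a), h), "bu": np.zeros(a),
            "w": init((a,), a), "bw": np.zeros(()),
            "Wc": np.zeros((h, 2)), "bc": np.zeros(2),
            "Wi": np.zeros((h, 2)), "bi": np.zeros(2),
        }

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.PARAM_NAMES:
            self.params[k] = params[k].copy()


@dataclass
class AttentionOutput:
    raw_attention: np.ndarray       # (n,), nonnegative, sums to 1
    normalized_score: np.ndarray    # (n,), in [0, 1] (within-slide percentile rank)
    bag_logits: np.ndarray          # (2,)
    wsi_score: float                # P(recurrence), in [0, 1]


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


class EarlyStopping:
    """Patience-based stopping on validation loss.

    An epoch "improves" iff its loss is strictly smaller than the running
    minimum; ties do not reset patience.  Stop after ``patience`` consecutive
    non-improving epochs.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.counter = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record ``loss`` for 1-based ``epoch``; return True if training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.counter = 0
        else:
            self.counter += 1
        return self.counter >= self.patience


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _forward(params: dict, X: np.ndarray, drop_mask: np.ndarray | None = None) -> dict:
    """Shared forward pass; returns all intermediates needed for backprop.

    ``drop_mask`` is a pre-scaled inverted-dropout mask applied to the
    patch embedding during training steps only.
    """
    Z = X @ params["Wp"] + params["bp"]
    H = np.maximum(Z, 0.0)
    if drop_mask is not None:
        H = H * drop_mask
    T = np.tanh(H @ params["Wv"] + params["bv"])
    S = 1.0 / (1.0 + np.exp(-(H @ params["Wu"] + params["bu"])))
    G = T * S
    e = G @ params["w"] + params["bw"]
    a = _softmax(e)
    M = a @ H
    logits = M @ params["Wc"] + params["bc"]
    return {"X": X, "Z": Z, "H": H, "T": T, "S": S, "G": G, "e": e,
            "a": a, "M": M, "logits": logits}


def attention_weights(model: MILModel, bag: PatchBag) -> np.ndarray:
    """Per-patch gated-attention weights: nonnegative, sum to 1,
    permutation-equivariant in the patch order."""
    X = _check_bag(model, bag)
    return _forward(model.params, X)["a"]


def normalize_attention(raw: np.ndarray) -> np.ndarray:
    """Within-slide percentile rank of the raw attention: rank/(n-1) with
    average ranks for ties; a single patch scores 1.0."""
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    if n == 0:
        raise ValueError("empty attention vector")
    if n == 1:
        return np.ones(1)
    return (rankdata(raw, method="average") - 1.0) / (n - 1.0)


def _check_bag(model: MILModel, bag: PatchBag) -> np.ndarray:
    X = np.asarray(bag.features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.config.feature_dim:
        raise ValueError(
            f"bag {bag.case_id}: feature dim {X.shape[1] if X.ndim == 2 else '?'} "
            f"does not match model feature_dim {model.config.feature_dim}")
    if X.shape[0] == 0:
        raise ValueError(f"bag {bag.case_id}: empty bag")
    return X


def bag_forward(model: MILModel, bag: PatchBag) -> AttentionOutput:
    """Full bag prediction: attention, bag embedding, logits and WSI score."""
    X = _check_bag(model, bag)
    f = _forward(model.params, X)
    p = _softmax(f["logits"])
    return AttentionOutput(
        raw_attention=f["a"],
        normalized_score=normalize_attention(f["a"]),
        bag_logits=f["logits"],
        wsi_score=float(p[1]))


def predict_wsi_score(model: MILModel, bag: PatchBag) -> float:
    """Bag-level recurrence probability (the "WSI score")."""
    return bag_forward(model, bag).wsi_score


def _instance_indices(a: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k / bottom-k attention indices with k reduced to floor(n/2)."""
    n = a.shape[0]
    k = max(1, min(k, n // 2)) if n >= 2 else 0
    if k == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(a, kind="stable")
    return order[-k:], order[:k]


def instance_loss(model: MILModel, bag: PatchBag, label: int, k: int | None = None) -> float:
    """Cross-entropy of the instance classifier on attention pseudo-labels:
    top-k patches take the bag's class, bottom-k the complement class."""
    X = _check_bag(model, bag)
    f = _forward(model.params, X)
    k = model.config.instance_k if k is None else k
    top, bot = _instance_indices(f["a"], k)
    if top.size == 0:
        return 0.0
    idx = np.concatenate([top, bot])
    targets = np.concatenate([np.full(top.size, int(label)),
                              np.full(bot.size, 1 - int(label))])
    logits = f["H"][idx] @ model.params["Wi"] + model.params["bi"]
    logp = logits - _logsumexp(logits)
    return float(-logp[np.arange(idx.size), targets].mean())


def _logsumexp(z: np.ndarray) -> np.ndarray:
    m = z.max(axis=1, keepdims=True)
    return m + np.log(np.exp(z - m).sum(axis=1, keepdims=True))


def bag_loss_and_grads(params: dict, X: np.ndarray, label: int,
                       c1: float, c2: float, instance_k: int,
                       drop_mask: np.ndarray | None = None) -> tuple[float, dict]:
    """Combined loss ``c1*bagCE + c2*instanceCE`` and its exact gradients."""
    f = _forward(params, X, drop_mask)
    n = X.shape[0]
    y = int(label)

    # bag cross-entropy
    logits = f["logits"]
    m = logits.max()
    lse = m + np.log(np.exp(logits - m).sum())
    p = np.exp(logits - lse)
    loss_bag = float(lse - logits[y])

    # instance branch
    top, bot = _instance_indices(f["a"], instance_k)
    idx = np.concatenate([top, bot])
    if idx.size:
        targets = np.concatenate([np.full(top.size, y), np.full(bot.size, 1 - y)])
        ilogits = f["H"][idx] @ params["Wi"] + params["bi"]
        ilogp = ilogits - _logsumexp(ilogits)
        loss_inst = float(-ilogp[np.arange(idx.size), targets].mean())
    else:
        loss_inst = 0.0

    loss = c1 * loss_bag + c2 * loss_inst

    grads = {k: None for k in params}
    # --- bag branch backward ---
    dlogits = c1 * (p - np.eye(2)[y])                       # (2,)
    grads["Wc"] = np.outer(f["M"], dlogits)
    grads["bc"] = dlogits
    dM = params["Wc"] @ dlogits                              # (h,)
    da = f["H"] @ dM                                         # (n,)
    dH = np.outer(f["a"], dM)                                # (n,h)
    # softmax backward
    de = f["a"] * (da - float(f["a"] @ da))                  # (n,)
    dG = np.outer(de, params["w"])                           # (n,a)
    grads["w"] = f["G"].T @ de
    grads["bw"] = np.array(de.sum())
    dT = dG * f["S"]
    dS = dG * f["T"]
    dZv = dT * (1.0 - f["T"] ** 2)
    dZu = dS * f["S"] * (1.0 - f["S"])
    grads["Wv"] = f["H"].T @ dZv
    grads["bv"] = dZv.sum(axis=0)
    grads["Wu"] = f["H"].T @ dZu
    grads["bu"] = dZu.sum(axis=0)
    dH += dZv @ params["Wv"].T + dZu @ params["Wu"].T

    # --- instance branch backward (selection indices treated as constant) ---
    if idx.size:
        ip = np.exp(ilogp)
        dilogits = c2 * (ip - np.eye(2)[targets]) / idx.size  # (2k,2)
        grads["Wi"] = f["H"][idx].T @ dilogits
        grads["bi"] = dilogits.sum(axis=0)
        dH[idx] += dilogits @ params["Wi"].T
    else:
        grads["Wi"] = np.zeros_like(params["Wi"])
        grads["bi"] = np.zeros_like(params["bi"])

    # --- projection backward ---
    if drop_mask is not None:
        dH = dH * drop_mask
    dZ = dH * (f["Z"] > 0)
    grads["Wp"] = X.T @ dZ
    grads["bp"] = dZ.sum(axis=0)
    return loss, grads


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _eval_loss(model: MILModel, bags: Sequence[PatchBag], labels: Sequence[int]) -> float:
    c = model.config
    total = 0.0
    for bag, y in zip(bags, labels):
        X = _check_bag(model, bag)
        loss, _ = bag_loss_and_grads(model.params, X, int(y),
                                     c.bag_loss_weight, c.instance_loss_weight,
                                     c.instance_k)
        total += loss
    return total / len(bags)


def train_mil(train_bags: Sequence[PatchBag], train_labels: Sequence[int],
              val_bags: Sequence[PatchBag], val_labels: Sequence[int],
              config: MILConfig) -> tuple[MILModel, TrainHistory]:
    """Train with Adam, one step per bag, early stopping on validation loss.

    Returns the model with parameters restored from the best epoch.
    Raises if either split is empty or single-class.
    """
    config.validate()
    train_labels = [int(y) for y in train_labels]
    val_labels = [int(y) for y in val_labels]
    for name, labels in (("train", train_labels), ("validation", val_labels)):
        if len(labels) == 0 or len(set(labels)) < 2:
            raise ValueError(f"{name} split must be non-empty and contain both classes")

    model = MILModel(config)
    opt = _Adam(model.params, config.learning_rate)
    rng = np.random.default_rng(config.seed)
    stopper = EarlyStopping(config.patience)
    history = TrainHistory()
    best_params = model.copy_params()

    Xs = [_check_bag(model, b) for b in train_bags]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(Xs))
        running = 0.0
        for i in order:
            mask = None
            if config.dropout_rate > 0.0:
                keep = 1.0 - config.dropout_rate
                mask = (rng.random((Xs[i].shape[0], config.hidden_dim)) < keep) / keep
            loss, grads = bag_loss_and_grads(
                model.params, Xs[i], train_labels[i],
                config.bag_loss_weight, config.instance_loss_weight,
                config.instance_k, drop_mask=mask)
            opt.step(model.params, grads)
            running += loss
        history.train_loss.append(running / len(Xs))
        vloss = _eval_loss(model, val_bags, val_labels)
        history.val_loss.append(vloss)
        stop = stopper.update(epoch, vloss)
        if stopper.best_epoch == epoch:
            best_params = model.copy_params()
        if stop:
            history.stopped_epoch = epoch
            break
    else:
        history.stopped_epoch = config.max_epochs
    history.best_epoch = stopper.best_epoch
    model.set_params(best_params)
    return model, history


# ---------------------------------------------------------------------------
# checkpointing

def save_model(model: MILModel, path) -> None:
    """Single-file checkpoint: config echo + parameter arrays + version."""
    meta = {"version": CHECKPOINT_VERSION, "config": model.config.__dict__}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_model(path) -> MILModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        config = MILConfig(**meta["config"])
        model = MILModel(config)
        for k in MILModel.PARAM_NAMES:
            model.params[k] = np.asarray(data[k], dtype=np.float64)
    return model
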