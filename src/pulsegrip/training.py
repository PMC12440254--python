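"""Training loop: SGD with Nesterov momentum, cosine annealing with
restarts, binary cross-entropy on per-class sigmoid scores.

The learning-rate schedule follows a half-cosine from the cycle's base rate
down to ``alpha * base`` over ``decay_steps`` optimizer steps; at each
restart the base rate is multiplied by ``restart_lr_mult`` (2 by default),
capped after ``max_restarts`` restarts to keep the geometric growth bounded.
The loss is binary cross-entropy against one-hot targets (each class scored
by an independent sigmoid); softmax cross-entropy is available as an
alternative.  Training is seeded end to end — initialization, shuffling and
dropout all derive from ``TrainConfig.seed`` — and the best model by
validation loss is kept.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from .network import CNNLSTM, ModelConfig, build_model
from .synthetic import LabeledDataset

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "lr_schedule",
    "bce_loss",
    "make_windows",
    "train",
]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 0.002
    momentum: float = 0.9  # Nesterov
    decay_steps: int = 50
    alpha: float = 0.0
    restart_lr_mult: float = 2.0
    max_restarts: int = 4
    batch_size: int = 128
    max_epochs: int = 100
    seed: int = 0
    loss: str = "bce"  # "bce" | "softmax_ce"
    patience: int | None = 25  # epochs without val-loss improvement

    def __post_init__(self) -> None:
        if not self.base_lr > 0:
            raise ValueError("base_lr must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.decay_steps < 1:
            raise ValueError("decay_steps must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("bce", "softmax_ce"):
            raise ValueError("loss must be 'bce' or 'softmax_ce'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Learning rate at a given optimizer step.

    Cycle k spans steps (k*decay_steps, (k+1)*decay_steps]; within it the
    rate follows alpha*b_k + (b_k - alpha*b_k) * 0.5*(1 + cos(pi*t/T)) with
    b_k = base_lr * restart_lr_mult**min(k, max_restarts).  Step 0 starts
    cycle 0 at the full base rate; each cycle ends at alpha*b_k.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    ds = config.decay_steps
    k = 0 if step == 0 else (step - 1) // ds
    b = config.base_lr * config.restart_lr_mult ** min(k, config.max_restarts)
    t = step - k * ds
    floor = config.alpha * b
    return floor + (b - floor) * 0.5 * (1.0 + np.cos(np.pi * t / ds))


def bce_loss(scores: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy of per-class scores vs one-hot targets."""
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if scores.shape != targets.shape:
        raise ValueError(f"shape mismatch: {scores.shape} vs {targets.shape}")
    s = np.clip(scores, _EPS, 1.0 - _EPS)
    return float(-np.mean(targets * np.log(s) + (1.0 - targets) * np.log(1.0 - s)))


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.size, n_classes), dtype=np.float32)
    out[np.arange(labels.size), labels] = 1.0
    return out


def make_windows(
    dataset: LabeledDataset, input_length: int, part: str | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tile trials into non-overlapping fixed-length windows.

    Returns (X, y, trial_index): windows share their trial's label and keep
    the originating trial index so predictions can be aggregated back.
    """
    idx = dataset.indices(part) if part is not None else np.arange(
        len(dataset.sequences)
    )
    xs, ys, tids = [], [], []
    for i in idx:
        x = dataset.sequences[i].samples
        n_win = x.size // input_length
        if n_win == 0:
            raise ValueError(
                f"sequence {i} of length {x.size} shorter than window "
                f"{input_length}"
            )
        for w in range(n_win):
            xs.append(x[w * input_length : (w + 1) * input_length])
            ys.append(dataset.labels[i])
            tids.append(i)
    return (
        np.asarray(xs, dtype=np.float32),
        np.asarray(ys, dtype=int),
        np.asarray(tids, dtype=int),
    )


def _batch_loss_and_grad(model, xb, yb, loss_kind):
    """Forward in train mode; return (loss, dlogits)."""
    z = model.forward_logits(xb, train=True)
    if loss_kind == "bce":
        s = 1.0 / (1.0 + np.exp(-z))
        loss = bce_loss(s, yb)
        dz = (s - yb) / z.size
    else:
        zmax = z.max(axis=1, keepdims=True)
        ez = np.exp(z - zmax)
        p = ez / ez.sum(axis=1, keepdims=True)
        loss = float(-np.mean(np.sum(yb * np.log(np.clip(p, _EPS, 1.0)), axis=1)))
        dz = (p - yb) / z.shape[0]
    return loss, dz.astype(np.float32)


def _eval_loss(model, X, y_onehot, loss_kind, batch_size=256):
    losses, weights = [], []
    for lo in range(0, X.shape[0], batch_size):
        xb = X[lo : lo + batch_size]
        yb = y_onehot[lo : lo + batch_size]
        z = model.forward_logits(xb, train=False)
        if loss_kind == "bce":
            s = 1.0 / (1.0 + np.exp(-z))
            losses.append(bce_loss(s, yb))
        else:
            zmax = z.max(axis=1, keepdims=True)
            ez = np.exp(z - zmax)
            p = ez / ez.sum(axis=1, keepdims=True)
            losses.append(
                float(-np.mean(np.sum(yb * np.log(np.clip(p, _EPS, 1.0)), axis=1)))
            )
        weights.append(xb.shape[0])
    return float(np.average(losses, weights=weights))


def train(
    model: CNNLSTM | None,
    dataset: LabeledDataset,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    log=sys.stderr,
) -> tuple[CNNLSTM, TrainHistory]:
    """Train the dual-path network on the train split; validate each epoch.

    The dataset must carry train and val splits (sequences are expected to
    be preprocessed).  If ``model`` is None one is built from
    ``model_config`` with the training seed.  The returned model carries the
    best-validation-loss parameters; history records per-epoch train loss,
    validation loss and the learning rate at the epoch's first step.
    """
    if dataset.split is None:
        raise ValueError("dataset must be split before training")
    if model is None:
        if model_config is None:
            raise ValueError("either model or model_config is required")
        model = build_model(model_config, seed=config.seed)
    input_length = model.config.input_length
    X_tr, y_tr, _ = make_windows(dataset, input_length, "train")
    X_val, y_val, _ = make_windows(dataset, input_length, "val")
    if X_tr.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("empty train or val split")
    n_classes = model.config.n_classes
    Y_tr = _one_hot(y_tr, n_classes)
    Y_val = _one_hot(y_val, n_classes)

    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 0x7EA1)))
    model.reseed_dropout(config.seed)
    batch = min(config.batch_size, X_tr.shape[0])
    if batch < config.batch_size and log is not None:
        print(
            f"[train] train set ({X_tr.shape[0]} windows) smaller than "
            f"batch_size {config.batch_size}; using full-batch updates",
            file=log,
        )

    velocity = {p.name: np.zeros_like(p.v) for p in model.parameters()}
    history = TrainHistory()
    best_val = np.inf
    best_state = model.state_dict()
    step = 0
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(X_tr.shape[0])
        epoch_losses, epoch_weights = [], []
        lr_epoch = lr_schedule(step, config)
        for lo in range(0, order.size, batch):
            sel = order[lo : lo + batch]
            lr = lr_schedule(step, config)
            loss, dz = _batch_loss_and_grad(
                model, X_tr[sel], Y_tr[sel], config.loss
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {step}"
                )
            model.zero_grad()
            model.backward(dz)
            mu = config.momentum
            for p in model.parameters():
                v = velocity[p.name]
                v *= mu
                v += p.g
                p.v -= (lr * (p.g + mu * v)).astype(np.float32)
            epoch_losses.append(loss)
            epoch_weights.append(sel.size)
            step += 1
        train_loss = float(np.average(epoch_losses, weights=epoch_weights))
        val_loss = _eval_loss(model, X_val, Y_val, config.loss)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.lr.append(float(lr_epoch))
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if log is not None:
            print(
                f"[train] epoch {epoch:3d} train {train_loss:.4f} "
                f"val {val_loss:.4f} lr {lr_epoch:.5f}",
                file=log,
            )
        if config.patience is not None and since_best >= config.patience:
            break
    model.load_state_dict(best_state)
    return model, history
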