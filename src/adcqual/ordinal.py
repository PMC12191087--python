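"""Ordinal quality scoring with CORN (Consistent Rank Logits) heads.

A network emits K-1 = 2 logits for the 3-point quality scale. Logit k
models the conditional exceedance P(y > k | y > k-1); the unconditional
exceedance probabilities are the cumulative product of the conditional
sigmoids, which makes the rank probabilities monotone by construction.
Quality 1 is "non-diagnostic" (the screening-positive class), 3 is optimal.

Training uses the class-weighted CORN loss, Adam with decoupled weight
decay, a cosine-annealed learning rate, the two-pass adaptive
sharpness-aware (ASAM) update, and early stopping on held-out binary AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._net import Adam, ConvNet, asam_perturbation, cosine_lr, sigmoid
from .metrics import binary_auc
from .preprocess import AugmentConfig, augment_batch

log = logging.getLogger(__name__)

N_LEVELS = 3

BACKBONES = {
    # name -> (channels, first_kernel, hidden)
    "small_cnn": ((8, 16, 32, 32), 3, 32),
    "wide_cnn": ((12, 24, 48, 48), 5, 48),
}


@dataclass
class OrdinalPrediction:
    """Per-image CORN output."""

    cum_probs: np.ndarray  # unconditional exceedance P(y > k), k = 1, 2
    rank: int
    binary_nondx_prob: float


def corn_logits_to_prediction(logits: np.ndarray) -> OrdinalPrediction:
    """Convert K-1 conditional logits to exceedance probabilities and rank."""
    logits = np.asarray(logits, float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    cum = np.cumprod(sigmoid(logits))
    rank = 1 + int(np.sum(cum > 0.5))
    return OrdinalPrediction(
        cum_probs=cum, rank=rank, binary_nondx_prob=float(1.0 - cum[0])
    )


def corn_cum_probs(logits: np.ndarray) -> np.ndarray:
    """Vectorized exceedance probabilities for a (N, K-1) logit batch."""
    return np.cumprod(sigmoid(np.atleast_2d(logits)), axis=1)


def class_weights(labels, multiplier: float = 5.0) -> np.ndarray:
    """Inverse-frequency class weights, the lowest-quality class boosted by
    ``multiplier``, normalized to mean 1."""
    labels = np.asarray(labels)
    counts = np.array([(labels == k).sum() for k in range(1, N_LEVELS + 1)], float)
    missing = [k + 1 for k in range(N_LEVELS) if counts[k] == 0]
    if missing:
        raise ValueError(f"no examples of quality class(es) {missing}")
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    w = 1.0 / counts
    w[0] *= multiplier
    return w / w.mean()


def _corn_terms(logits, labels, weights):
    logits = np.atleast_2d(np.asarray(logits, float))
    labels = np.asarray(labels)
    n, km1 = logits.shape
    if labels.shape[0] != n:
        raise ValueError("logits and labels batch sizes differ")
    if km1 != N_LEVELS - 1:
        raise ValueError(f"expected {N_LEVELS - 1} logits per example")
    w = np.ones(N_LEVELS) if weights is None else np.asarray(weights, float)
    wi = w[labels - 1]
    ks = np.arange(1, N_LEVELS)  # tasks 1..K-1
    mask = labels[:, None] > (ks - 1)[None, :]  # participate in task k iff y > k-1
    target = (labels[:, None] > ks[None, :]).astype(float)
    return logits, wi, mask, target


def corn_loss(logits, labels, weights=None) -> float:
    """Class-weighted CORN loss: conditional-subset binary cross-entropy,
    averaged over the contributing (example, task) terms."""
    logits, wi, mask, target = _corn_terms(logits, labels, weights)
    # stable BCE with logits: max(z,0) - z*t + log(1+exp(-|z|))
    z = logits
    bce = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    n_terms = mask.sum()
    return float((wi[:, None] * bce * mask).sum() / n_terms)


def corn_loss_grad(logits, labels, weights=None):
    """(loss, dloss/dlogits) for the weighted CORN loss."""
    logits, wi, mask, target = _corn_terms(logits, labels, weights)
    z = logits
    bce = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    n_terms = mask.sum()
    loss = float((wi[:, None] * bce * mask).sum() / n_terms)
    grad = wi[:, None] * (sigmoid(z) - target) * mask / n_terms
    return loss, grad


def build_backbone(name: str, input_px: int, seed: int = 0) -> ConvNet:
    """Construct a compact CNN backbone ending in a (K-1)-logit CORN head."""
    if name not in BACKBONES:
        raise ValueError(
            f"unknown backbone {name!r}; available: {sorted(BACKBONES)}"
        )
    channels, fk, hidden = BACKBONES[name]
    return ConvNet(input_px, channels=channels, first_kernel=fk,
                   hidden=hidden, n_out=N_LEVELS - 1, seed=seed)


@dataclass
class TrainConfig:
    backbone: str = "small_cnn"
    lr_init: float = 5e-5
    lr_min: float = 1e-6
    weight_decay: float = 1e-2
    asam_rho: float = 0.5
    epochs: int = 5
    batch_size: int = 128
    lowest_class_multiplier: float = 5.0
    early_stop_patience: int = 10
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must not exceed lr_init")
        if self.lowest_class_multiplier < 1:
            raise ValueError("lowest_class_multiplier must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class Dataset:
    """Slice-level training examples for one (modality, region) network."""

    X: np.ndarray  # (N, H, W) float32 in [0, 1]
    y: np.ndarray  # (N,) ordinal labels in {1, 2, 3}
    patient_ids: np.ndarray  # (N,) strings

    def __len__(self):
        return len(self.y)


@dataclass
class TrainResult:
    model: ConvNet
    log: list  # per-epoch dicts: epoch, lr, train_loss, test_auc
    best_epoch: int
    best_auc: float


def save_checkpoint(model: ConvNet, path, *, backbone: str, config=None,
                    log=None) -> None:
    """Persist model weights plus config and training log (npz + JSON)."""
    import json

    meta = {
        "backbone": backbone,
        "input_px": model.input_px,
        "config": None if config is None else {
            k: (v.__dict__ if hasattr(v, "__dict__") else v)
            for k, v in config.__dict__.items()
        },
        "log": log,
    }
    arrays = {f"p{i}": p for i, p in enumerate(model.get_params())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path):
    """Restore a model saved by :func:`save_checkpoint`.

    Returns ``(model, meta)`` where meta carries the backbone name, config
    snapshot and training log."""
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    model = build_backbone(meta["backbone"], meta["input_px"])
    model.set_params([data[f"p{i}"] for i in range(len(model.get_params()))])
    return model, meta


def predict_cum_probs(model: ConvNet, X: np.ndarray, batch: int = 512) -> np.ndarray:
    """Exceedance probabilities for a (N, H, W) image array."""
    outs = []
    for i in range(0, len(X), batch):
        logits = model.forward(X[i : i + batch][:, None, :, :])
        outs.append(corn_cum_probs(logits))
    return np.vstack(outs) if outs else np.zeros((0, N_LEVELS - 1))


def train(model: ConvNet, train_data: Dataset, test_data: Dataset,
          config: TrainConfig) -> TrainResult:
    """ASAM/Adam training with cosine-annealed lr and AUC early stopping.

    Each step takes the two-pass ASAM update: gradients at the adaptively
    scaled ascent point drive an Adam step at the original weights. After
    every epoch the binary AUC (non-diagnostic vs diagnostic) on the test
    split is logged; the returned model carries the weights of the best
    test-AUC epoch. Train and test patients must be disjoint.
    """
    overlap = set(train_data.patient_ids) & set(test_data.patient_ids)
    if overlap:
        raise ValueError(f"patient leakage between train and test: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(config.seed)
    weights = class_weights(train_data.y, config.lowest_class_multiplier)
    opt = Adam(model, weight_decay=config.weight_decay)
    y_test_bin = (test_data.y == 1).astype(int)

    best_auc, best_epoch, best_params = -np.inf, -1, model.copy_params()
    history = []
    since_improve = 0
    n = len(train_data)
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr_init, config.lr_min)
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb = train_data.X[idx]
            if config.augment is not None:
                xb = augment_batch(xb, rng, config.augment)
            xb = xb[:, None, :, :].astype(np.float32)
            yb = train_data.y[idx]

            logits = model.forward(xb, train=True)
            loss, dlogits = corn_loss_grad(logits, yb, weights)
            model.backward(dlogits)
            grads = model.gradients()

            if config.asam_rho > 0:
                params = model.get_params()
                eps = asam_perturbation(params, grads, config.asam_rho)
                saved = model.copy_params()
                for p, e in zip(params, eps):
                    p += e.astype(np.float32)
                logits2 = model.forward(xb, train=True)
                _, dlogits2 = corn_loss_grad(logits2, yb, weights)
                model.backward(dlogits2)
                grads = [g.copy() for g in model.gradients()]
                model.set_params(saved)

            opt.step(grads, lr)
            losses.append(loss)

        cum = predict_cum_probs(model, test_data.X)
        scores = 1.0 - cum[:, 0]  # P(non-diagnostic)
        auc = binary_auc(scores, y_test_bin) if len(set(y_test_bin)) > 1 else np.nan
        history.append({
            "epoch": epoch, "lr": float(lr),
            "train_loss": float(np.mean(losses)), "test_auc": float(auc),
        })
        if np.isfinite(auc) and auc > best_auc:
            best_auc, best_epoch = float(auc), epoch
            best_params = model.copy_params()
            since_improve = 0
        else:
            since_improve += 1
        if since_improve >= config.early_stop_patience:
            log.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break

    model.set_params(best_params)
    return TrainResult(model=model, log=history, best_epoch=best_epoch,
                       best_auc=best_auc)
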