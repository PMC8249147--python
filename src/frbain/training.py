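"""Gradient-based learning of the E-FRBAIN parameters and evaluation.

Only the closed-form layer chain is differentiated: DTW distances from every
training record to the (frozen) kernel centers are computed once up front,
so each epoch is distance-free.  The trainable parameters are the per-neuron
kernel parameters (sigma, a, c) and the T-S head (W, r); the loss is mean
categorical cross-entropy against the softmax class scores.  After every
optimiser step sigma is projected above 1e-6 and c back into [0, 1).

The learning-rate schedule is a step decay:
``lr(epoch) = initial_lr * factor^floor(epoch / decay_every)`` — with the
defaults (0.5, x0.1 every 50 epochs) the rate is 0.5 at epoch 0, 0.05 at 50
and 0.005 at 100.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import expit
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .clustering import KernelBank
from .dtw import dtw_distance
from .errors import DegenerateMembershipError, ValidationError
from .network import EFRBAINModel, Prediction, center_distances
from .signal import SignalDataset

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "MetricsReport",
    "precompute_distances",
    "loss",
    "learning_rate",
    "train",
    "predict_dataset",
    "evaluate",
]

logger = logging.getLogger(__name__)

_EPS_PROB = 1e-12
_SIGMA_FLOOR = 1e-6


@dataclass
class TrainingConfig:
    """Optimisation settings (defaults follow the step-decay regime)."""

    initial_lr: float = 0.5
    lr_decay_every: int = 50
    lr_decay_factor: float = 0.1
    max_epochs: int = 500
    batch_count: int = 50
    stop_loss: float = 0.005
    optimizer: str = "adam"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.max_epochs <= 0 or self.batch_count <= 0:
            raise ValidationError("learning rate, epochs and batch count must be positive")
        if not 0 < self.lr_decay_factor < 1:
            raise ValidationError("lr_decay_factor must lie in (0, 1)")
        if self.lr_decay_every <= 0 or self.stop_loss <= 0:
            raise ValidationError("lr_decay_every and stop_loss must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValidationError("optimizer must be 'adam' or 'sgd'")


@dataclass
class TrainingHistory:
    loss: List[float] = field(default_factory=list)
    lr: List[float] = field(default_factory=list)
    stop_reason: str = "max_epochs"

    @property
    def n_epochs(self) -> int:
        return len(self.loss)


@dataclass
class MetricsReport:
    """Per-class and macro precision/recall/F1 plus the confusion matrix."""

    classes: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    confusion: np.ndarray


def learning_rate(epoch: int, config: TrainingConfig) -> float:
    """Step-decay schedule, exact by construction."""
    return config.initial_lr * config.lr_decay_factor ** (epoch // config.lr_decay_every)


def precompute_distances(dataset: SignalDataset, bank_or_model,
                         dtw_options: Optional[dict] = None) -> np.ndarray:
    """(N, m) table of DTW distances from each record to each kernel center."""
    if isinstance(bank_or_model, EFRBAINModel):
        centers = bank_or_model.bank.centers
        opts = bank_or_model.dtw_options
    else:
        centers = bank_or_model.centers
        opts = dict(dtw_options or {})
    normalize = opts.get("normalize", False)
    band = opts.get("band")
    out = np.empty((len(dataset), len(centers)))
    for i, sig in enumerate(dataset):
        for j, z in enumerate(centers):
            out[i, j] = dtw_distance(sig, z, normalize=normalize, band=band,
                                     return_path=normalize).distance
    return out


def loss(probabilities: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy (natural log, clipped at 1e-12)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=int)
    if p.ndim == 1:
        p = p[None, :]
    if p.shape[0] != y.shape[0]:
        raise ValidationError("prediction/label batch sizes differ")
    return float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], _EPS_PROB, 1.0))))


def _class_indicator(class_index: np.ndarray, K: int) -> np.ndarray:
    M = np.zeros((len(class_index), K))
    M[np.arange(len(class_index)), class_index] = 1.0
    return M


def _batch_forward(dists: np.ndarray, params: Dict[str, np.ndarray],
                   class_index: np.ndarray, counts: np.ndarray) -> dict:
    """Vectorised forward pass (sum pooling) over a batch of distance rows.

    Returns every intermediate needed for backprop.  Raises if any record's
    memberships all clamp to zero.
    """
    sigma, a, c = params["sigma"], params["a"], params["c"]
    W, r = params["W"], params["r"]
    K = counts.shape[1]
    d2 = dists ** 2
    g = expit(a[None, :] - d2 / sigma[None, :] ** 2)  # (B, m)
    mu_raw = g - c[None, :]
    mu = np.clip(mu_raw, 0.0, 1.0)
    interior = (mu_raw > 0.0) & (mu_raw < 1.0)
    S = mu.sum(axis=1)
    if np.any(S <= 0):
        bad = np.nonzero(S <= 0)[0]
        raise DegenerateMembershipError(
            f"records at batch positions {bad.tolist()} match no kernel center"
        )
    h = mu / S[:, None]
    M = _class_indicator(class_index, K)
    q = h @ M  # (B, K), on the simplex
    qpow = q[:, None, :] ** counts[None, :, :]  # (B, L, K)
    z = qpow.prod(axis=2)  # (B, L)
    Z = z.sum(axis=1)
    qn = z / Z[:, None]
    scores = qn @ W + r[None, :]
    scores = scores - scores.max(axis=1, keepdims=True)
    ez = np.exp(scores)
    p = ez / ez.sum(axis=1, keepdims=True)
    return dict(d2=d2, g=g, mu=mu, interior=interior, S=S, h=h, M=M, q=q,
                qpow=qpow, z=z, Z=Z, qn=qn, p=p)


def loss_and_gradients(
    dists: np.ndarray,
    y: np.ndarray,
    params: Dict[str, np.ndarray],
    class_index: np.ndarray,
    counts: np.ndarray,
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Mean cross-entropy over the batch and its analytic gradients with
    respect to sigma, a, c, W and r.

    The clamp in the membership function is handled by a zero subgradient
    outside the interior; the product-rule layer gradient uses the exact
    multiplicity form d z_t / d q_k = n_tk q_k^(n_tk - 1) prod_{k' != k}
    q_k'^(n_tk').
    """
    cache = _batch_forward(dists, params, class_index, counts)
    B = dists.shape[0]
    K = counts.shape[1]
    y = np.asarray(y, dtype=int)
    Y = np.zeros((B, K))
    Y[np.arange(B), y] = 1.0
    p, qn, z, Z, qpow, q = (cache[k] for k in ("p", "qn", "z", "Z", "qpow", "q"))
    h, S, mu, interior, g, d2 = (cache[k] for k in ("h", "S", "mu", "interior", "g", "d2"))
    M = cache["M"]
    sigma = params["sigma"]
    batch_loss = loss(p, y)

    ds = (p - Y) / B  # (B, K) — softmax + CE combined
    dW = qn.T @ ds
    dr = ds.sum(axis=0)
    dqn = ds @ params["W"].T  # (B, L)
    dz = (dqn - np.sum(dqn * qn, axis=1, keepdims=True)) / Z[:, None]
    # product rule: per class, the product over all tuple slots except one
    # occurrence of that class
    nm1 = np.maximum(counts - 1, 0)
    dzdq = np.empty_like(qpow)  # (B, L, K)
    for k in range(K):
        others = np.prod(np.delete(qpow, k, axis=2), axis=2)  # (B, L)
        dzdq[:, :, k] = counts[None, :, k] * q[:, None, k] ** nm1[None, :, k] * others
    dq = np.einsum("bl,blk->bk", dz, dzdq)
    dh = dq @ M.T  # (B, m)
    dmu = (dh - np.sum(dh * h, axis=1, keepdims=True)) / S[:, None]
    dmu = np.where(interior, dmu, 0.0)
    gg = g * (1.0 - g)
    da = np.sum(dmu * gg, axis=0)
    dc = -np.sum(dmu, axis=0)
    dsigma = np.sum(dmu * gg * (2.0 * d2 / sigma[None, :] ** 3), axis=0)
    return batch_loss, {"sigma": dsigma, "a": da, "c": dc, "W": dW, "r": dr}


class _Adam:
    def __init__(self, shapes: Dict[str, tuple], beta1: float, beta2: float,
                 eps: float) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, grad in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


_LIVENESS_FLOOR = 0.05


def _project(params: Dict[str, np.ndarray],
             d2_all: Optional[np.ndarray] = None, eps: float = 1e-6) -> None:
    """Project parameters back onto their constraint sets.

    Box constraints: sigma above a small floor, c in [0, 1).  Two further
    projections keep the optimisation well-posed, because the clamped
    membership region has a zero subgradient and is therefore absorbing —
    an aggressive step that strands a neuron or a record there would leave
    no restoring gradient:

    * *kernel liveness*: each neuron's membership evaluated at its own
      kernel center, ``sigmoid(a_j) - c_j``, must stay at or above a small
      floor (0.05).  The offset c_j is pulled down first; if the sigmoid
      itself has saturated, a_j is raised to the boundary.
    * *record feasibility* (when the squared training-distance table is
      supplied): every training record must keep at least one positive
      membership; otherwise c at the record's best-matching neuron is
      lowered just enough.
    """
    np.maximum(params["sigma"], _SIGMA_FLOOR, out=params["sigma"])
    np.clip(params["c"], 0.0, 1.0 - 1e-9, out=params["c"])
    a, c = params["a"], params["c"]
    g0 = expit(a)
    viol = g0 - c < _LIVENESS_FLOOR
    if np.any(viol):
        c[viol] = np.maximum(0.0, g0[viol] - _LIVENESS_FLOOR)
        still = expit(a) - c < _LIVENESS_FLOOR
        if np.any(still):
            a[still] = np.log(_LIVENESS_FLOOR / (1.0 - _LIVENESS_FLOOR))
            c[still] = 0.0
    if d2_all is None:
        return
    g = expit(a[None, :] - d2_all / params["sigma"][None, :] ** 2)
    mu = g - c[None, :]
    for i in np.nonzero(mu.max(axis=1) < eps)[0]:
        j = int(np.argmax(g[i]))
        c[j] = max(0.0, min(c[j], g[i, j] - eps))


def train(
    model: EFRBAINModel,
    dataset: SignalDataset,
    config: Optional[TrainingConfig] = None,
    distances: Optional[np.ndarray] = None,
) -> Tuple[EFRBAINModel, TrainingHistory]:
    """Fit sigma, a, c, W, r by mini-batch gradient descent.

    Each epoch shuffles the records (seeded), splits them into
    ``batch_count`` batches (ragged last batches tolerated) and applies the
    optimiser per batch.  Training stops when the epoch mean loss drops
    below ``stop_loss`` or at ``max_epochs``.  The input model is not
    mutated; a trained copy is returned together with the history.
    ``distances`` may carry a precomputed record-to-center table.
    """
    config = config or TrainingConfig()
    if len(dataset) == 0:
        raise ValidationError("empty training dataset")
    if model.pooling != "sum":
        raise ValidationError("training supports sum pooling only")
    lut = {lab: k for k, lab in enumerate(model.class_order)}
    try:
        y = np.array([lut[s.label] for s in dataset], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"dataset label {exc} not among model classes")
    if distances is None:
        distances = precompute_distances(dataset, model)
    params = {
        "sigma": model.frbn.sigma.copy(),
        "a": model.frbn.shape_a.copy(),
        "c": model.frbn.offset_c.copy(),
        "W": model.ts.weights.copy(),
        "r": model.ts.bias.copy(),
    }
    counts = model.rules.counts
    class_index = model.bank.class_index
    rng = np.random.default_rng(config.seed)
    optimizer = None
    if config.optimizer == "adam":
        optimizer = _Adam({k: v.shape for k, v in params.items()},
                          config.adam_beta1, config.adam_beta2, config.adam_eps)
    history = TrainingHistory()
    n = len(dataset)
    n_batches = min(config.batch_count, n)
    d2_all = distances ** 2
    for epoch in range(config.max_epochs):
        lr = learning_rate(epoch, config)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for batch in np.array_split(order, n_batches):
            bl, grads = loss_and_gradients(
                distances[batch], y[batch], params, class_index, counts)
            epoch_loss += bl * len(batch)
            if config.optimizer == "adam":
                optimizer.step(params, grads, lr)
            else:
                for k, grad in grads.items():
                    params[k] -= lr * grad
            _project(params, d2_all)
        epoch_loss /= n
        history.loss.append(epoch_loss)
        history.lr.append(lr)
        logger.debug("epoch %d: loss=%.6f lr=%.4g", epoch, epoch_loss, lr)
        if epoch_loss < config.stop_loss:
            history.stop_reason = "converged"
            break
    else:
        history.stop_reason = "max_epochs"
    trained = copy.deepcopy(model)
    trained.frbn.sigma = params["sigma"]
    trained.frbn.shape_a = params["a"]
    trained.frbn.offset_c = params["c"]
    trained.ts.weights = params["W"]
    trained.ts.bias = params["r"]
    return trained, history


def predict_dataset(
    model: EFRBAINModel,
    dataset: SignalDataset,
    distances: Optional[np.ndarray] = None,
) -> List[Prediction]:
    """Forward every record through the model (distances precomputable)."""
    from .network import (pattern_layer, regularize, rule_layer, ts_classify,
                          frbn_membership)

    if distances is None:
        distances = precompute_distances(dataset, model)
    preds = []
    for i in range(len(dataset)):
        mu = frbn_membership(distances[i], model.frbn.sigma,
                             model.frbn.shape_a, model.frbn.offset_c)
        h = regularize(mu)
        q = pattern_layer(h, model.bank, mode=model.pooling)
        qn = regularize(rule_layer(q, model.rules))
        p = ts_classify(qn, model.ts)
        preds.append(Prediction(label=model.class_order[int(np.argmax(p))],
                                class_scores=p, frbn_memberships=mu,
                                pattern_memberships=q, rule_activations=qn))
    return preds


def evaluate(
    model: EFRBAINModel,
    dataset: SignalDataset,
    distances: Optional[np.ndarray] = None,
) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class, macro averages, accuracy
    and the K x K confusion matrix on a labeled dataset."""
    if any(s.label is None for s in dataset):
        raise ValidationError("evaluation requires labeled records")
    preds = predict_dataset(model, dataset, distances=distances)
    lut = {lab: k for k, lab in enumerate(model.class_order)}
    try:
        y_true = np.array([lut[s.label] for s in dataset], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"label {exc} not among model classes")
    y_pred = np.array([lut[p.label] for p in preds], dtype=int)
    K = len(model.class_order)
    labels = np.arange(K)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0)
    if np.any(support == 0) or np.any(np.bincount(y_pred, minlength=K) == 0):
        logger.warning("a class has zero support or zero predictions; its "
                       "metrics are reported as 0")
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return MetricsReport(
        classes=list(model.class_order),
        precision=prec, recall=rec, f1=f1, support=support,
        macro_precision=float(prec.mean()), macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        accuracy=float(np.trace(cm) / cm.sum()),
        confusion=cm,
    )
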