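"""The extended fuzzy radial basis adaptive inference network (E-FRBAIN).

Forward pipeline for one record X:

1. *Fuzzification*: each fuzzy radial basis neuron j holds a kernel-center
   signal Z_j and emits a membership degree
   ``mu_j = clip(sigmoid(a_j - d^2/sigma_j^2) - c_j, 0, 1)`` where d is the
   DTW distance between X and Z_j, sigma_j a smoothing width in distance
   units and (a_j, c_j) morphological parameters.
2. *Regularisation I*: the m memberships are normalised onto the simplex.
3. *Pattern layer*: per-class pooling (sum by default, max optional) of the
   normalised memberships gives K class membership degrees q_k.
4. *Rule layer*: every K-tuple over the K pattern nodes is a fuzzy rule with
   product t-norm firing strength, L = K^K rules in lexicographic order.
   With sum pooling the firing strengths already sum to one.
5. *Regularisation II* renormalises the firing strengths.
6. *T-S classifier head*: an affine map of the L activation intensities to K
   class scores followed by softmax.

The kernel centers are frozen training records (the model's embedded prior
knowledge); only (sigma, a, c) and the head (W, r) are trainable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Union

import numpy as np
from scipy.special import expit, softmax

from .clustering import KernelBank
from .dtw import dtw_distance
from .errors import (
    DataIOError,
    DegenerateMembershipError,
    DimensionError,
    StructureError,
    ValidationError,
)
from .signal import Signal

__all__ = [
    "FRBNParams",
    "RuleIndex",
    "TSParams",
    "EFRBAINModel",
    "Prediction",
    "frbn_membership",
    "fuzzify",
    "regularize",
    "pattern_layer",
    "rule_layer",
    "ts_classify",
    "forward",
    "build_model",
    "save_model",
    "load_model",
]

_ARCHIVE_VERSION = 1


@dataclass
class FRBNParams:
    """Per-neuron kernel parameters: widths and morphological shape."""

    sigma: np.ndarray
    shape_a: np.ndarray
    offset_c: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.shape_a = np.asarray(self.shape_a, dtype=float)
        self.offset_c = np.asarray(self.offset_c, dtype=float)
        if not (self.sigma.shape == self.shape_a.shape == self.offset_c.shape):
            raise ValidationError("FRBN parameter vectors must share a length")
        if np.any(self.sigma <= 0):
            raise ValidationError("sigma must be positive")
        if np.any((self.offset_c < 0) | (self.offset_c >= 1)):
            raise ValidationError("offset c must lie in [0, 1)")

    @property
    def m(self) -> int:
        return self.sigma.shape[0]


@dataclass
class RuleIndex:
    """Lexicographic enumeration of all K-tuples over the K pattern nodes."""

    n_classes: int
    tuples: np.ndarray = field(init=False)
    counts: np.ndarray = field(init=False)  # (L, K) multiplicity of class k

    def __post_init__(self) -> None:
        K = self.n_classes
        self.tuples = np.array(list(product(range(K), repeat=K)), dtype=int)
        L = self.tuples.shape[0]
        counts = np.zeros((L, K), dtype=int)
        for k in range(K):
            counts[:, k] = np.sum(self.tuples == k, axis=1)
        self.counts = counts

    @property
    def L(self) -> int:
        return self.tuples.shape[0]


@dataclass
class TSParams:
    """Affine head: rule-to-class weights (L, K) and class biases (K,)."""

    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 2 or self.bias.shape != (self.weights.shape[1],):
            raise ValidationError("T-S head shapes inconsistent")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ValidationError("T-S parameters must be finite")


@dataclass
class EFRBAINModel:
    """Assembled model: kernel bank plus all trainable parameters."""

    bank: KernelBank
    frbn: FRBNParams
    rules: RuleIndex
    ts: TSParams
    class_order: list
    dtw_options: dict = field(default_factory=dict)
    pooling: str = "sum"

    def __post_init__(self) -> None:
        if self.frbn.m != self.bank.m:
            raise ValidationError("FRBN parameter count must equal bank size")
        K = len(self.class_order)
        if self.rules.n_classes != K or self.ts.weights.shape != (self.rules.L, K):
            raise ValidationError("rule/head structure inconsistent with classes")
        if self.pooling not in ("sum", "max"):
            raise ValidationError("pooling must be 'sum' or 'max'")

    @property
    def m(self) -> int:
        return self.bank.m

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    @property
    def L(self) -> int:
        return self.rules.L


@dataclass
class Prediction:
    """Forward-pass output with every intermediate layer exposed."""

    label: object
    class_scores: np.ndarray  # K softmax probabilities
    frbn_memberships: np.ndarray  # m raw memberships in [0, 1]
    pattern_memberships: np.ndarray  # K pooled class memberships
    rule_activations: np.ndarray  # L normalised firing strengths


def frbn_membership(d, sigma, a, c):
    """Membership of a signal at DTW distance ``d`` from a kernel center.

    ``clip(sigmoid(a - d^2/sigma^2) - c, 0, 1)``: a decreasing sigmoid of
    the squared distance, maximal at the center, clamped to a valid
    membership.  Vectorises over any broadcastable arguments.
    """
    d = np.asarray(d, dtype=float)
    if np.any(np.asarray(sigma) <= 0):
        raise ValidationError("sigma must be positive")
    raw = expit(np.asarray(a, dtype=float) - d ** 2 / np.asarray(sigma, dtype=float) ** 2)
    return np.clip(raw - np.asarray(c, dtype=float), 0.0, 1.0)


def center_distances(x: Union[Signal, np.ndarray], model: EFRBAINModel) -> np.ndarray:
    """DTW distance from one record to every kernel center, bank order."""
    vals = x.values if isinstance(x, Signal) else np.asarray(x, dtype=float)
    if vals.ndim == 1:
        vals = vals[None, :]
    if vals.shape[0] != model.bank.centers[0].n_channels:
        raise DimensionError(
            f"record has {vals.shape[0]} channels, bank expects "
            f"{model.bank.centers[0].n_channels}"
        )
    opts = model.dtw_options
    return np.array([
        dtw_distance(vals, z, normalize=opts.get("normalize", False),
                     band=opts.get("band"), return_path=opts.get("normalize", False)
                     ).distance
        for z in model.bank.centers
    ])


def fuzzify(x: Union[Signal, np.ndarray], model: EFRBAINModel) -> np.ndarray:
    """Raw FRBN memberships of a record against every kernel center."""
    d = center_distances(x, model)
    return frbn_membership(d, model.frbn.sigma, model.frbn.shape_a,
                           model.frbn.offset_c)


def regularize(v: np.ndarray) -> np.ndarray:
    """Normalise nonnegative layer outputs onto the membership simplex."""
    v = np.asarray(v, dtype=float)
    total = v.sum()
    if total <= 0:
        raise DegenerateMembershipError(
            "all memberships are zero; the record matches no kernel center"
        )
    return v / total


def pattern_layer(h: np.ndarray, bank: KernelBank, mode: str = "sum") -> np.ndarray:
    """Pool normalised FRBN outputs per class: q_k = sum (or max) over the
    bank indices belonging to class k."""
    h = np.asarray(h, dtype=float)
    if h.shape[0] != bank.m:
        raise ValidationError("membership vector length must equal bank size")
    K = bank.n_classes
    q = np.zeros(K)
    if mode == "sum":
        np.add.at(q, bank.class_index, h)
    elif mode == "max":
        for k in range(K):
            q[k] = h[bank.class_index == k].max()
    else:
        raise ValidationError("mode must be 'sum' or 'max'")
    return q


def rule_layer(q: np.ndarray, rules: RuleIndex) -> np.ndarray:
    """Product t-norm firing strength of every rule:
    z_t = prod_v q_{tuple_t[v]} over the L = K^K lexicographic tuples."""
    q = np.asarray(q, dtype=float)
    if q.shape[0] != rules.n_classes:
        raise ValidationError("pattern vector length must equal class count")
    return np.prod(q[rules.tuples], axis=1)


def ts_classify(qn: np.ndarray, ts: TSParams) -> np.ndarray:
    """Affine map of rule activation intensities to class scores, softmaxed."""
    qn = np.asarray(qn, dtype=float)
    scores = qn @ ts.weights + ts.bias
    return softmax(scores)


def forward(x: Union[Signal, np.ndarray], model: EFRBAINModel) -> Prediction:
    """Full forward pass; argmax label with ties to the earlier class."""
    mu = fuzzify(x, model)
    h = regularize(mu)
    q = pattern_layer(h, model.bank, mode=model.pooling)
    z = rule_layer(q, model.rules)
    qn = regularize(z)
    p = ts_classify(qn, model.ts)
    label = model.class_order[int(np.argmax(p))]
    return Prediction(label=label, class_scores=p, frbn_memberships=mu,
                      pattern_memberships=q, rule_activations=qn)


def build_model(
    bank: KernelBank,
    seed: int = 0,
    a_init: float = 1.0,
    c_init: float = 0.0,
    weight_scale: float = 0.01,
    rule_cap: int = 10 ** 6,
    dtw_options: Optional[dict] = None,
    pooling: str = "sum",
) -> EFRBAINModel:
    """Assemble an untrained model around a kernel bank.

    sigma_j starts at the median DTW distance from center j to the other
    centers (1.0 when there is no other center), a_j at ``a_init``, c_j at
    ``c_init``; head weights are small seeded Gaussians, biases zero.
    """
    if bank.m == 0:
        raise ValidationError("empty kernel bank")
    K = bank.n_classes
    if K < 2:
        raise ValidationError("need at least 2 classes")
    if K ** K > rule_cap:
        raise StructureError(
            f"rule layer would need {K}^{K} nodes, exceeding the cap "
            f"{rule_cap}; reduce the number of classes"
        )
    opts = dict(dtw_options or {})
    m = bank.m
    sigma = np.ones(m)
    if m > 1:
        dmat = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                dmat[i, j] = dmat[j, i] = dtw_distance(
                    bank.centers[i], bank.centers[j],
                    normalize=opts.get("normalize", False),
                    band=opts.get("band"),
                    return_path=opts.get("normalize", False),
                ).distance
        for j in range(m):
            med = np.median(np.delete(dmat[j], j))
            sigma[j] = med if med > 0 else 1.0
    frbn = FRBNParams(sigma=sigma, shape_a=np.full(m, a_init),
                      offset_c=np.full(m, c_init))
    rules = RuleIndex(n_classes=K)
    rng = np.random.default_rng(seed)
    ts = TSParams(weights=rng.normal(0.0, weight_scale, size=(rules.L, K)),
                  bias=np.zeros(K))
    return EFRBAINModel(bank=bank, frbn=frbn, rules=rules, ts=ts,
                        class_order=list(bank.class_order),
                        dtw_options=opts, pooling=pooling)


def save_model(model: EFRBAINModel, path: str) -> str:
    """Write a model archive: ``params.json`` plus the bank's record files.

    JSON floats round-trip exactly, so a reloaded model reproduces forward
    passes bitwise.
    """
    os.makedirs(os.path.join(path, "bank"), exist_ok=True)
    bank_rows = []
    for i, sig in enumerate(model.bank.centers):
        fname = f"center_{i:04d}.csv"
        np.savetxt(os.path.join(path, "bank", fname), sig.values.T,
                   delimiter=",", fmt="%.17g")
        bank_rows.append({
            "class": int(model.bank.class_index[i]),
            "subclass": int(model.bank.subclass_index[i]),
            "record_id": sig.record_id,
            "file": fname,
        })
    payload = {
        "version": _ARCHIVE_VERSION,
        "class_order": [str(c) for c in model.class_order],
        "pooling": model.pooling,
        "dtw_options": model.dtw_options,
        "sigma": model.frbn.sigma.tolist(),
        "shape_a": model.frbn.shape_a.tolist(),
        "offset_c": model.frbn.offset_c.tolist(),
        "weights": model.ts.weights.tolist(),
        "bias": model.ts.bias.tolist(),
        "bank": bank_rows,
    }
    with open(os.path.join(path, "params.json"), "w") as fh:
        json.dump(payload, fh)
    return path


def load_model(path: str) -> EFRBAINModel:
    """Load a model archive written by :func:`save_model`."""
    params_path = os.path.join(path, "params.json")
    if not os.path.isfile(params_path):
        raise DataIOError(f"model archive missing params.json: {path}")
    try:
        with open(params_path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DataIOError(f"corrupt model archive {path}: {exc}")
    if payload.get("version") != _ARCHIVE_VERSION:
        raise DataIOError(
            f"unsupported model archive version {payload.get('version')!r}"
        )
    centers, cls_idx, sub_idx = [], [], []
    for row in payload["bank"]:
        vals = np.loadtxt(os.path.join(path, "bank", row["file"]),
                          delimiter=",", ndmin=2).T
        label = payload["class_order"][row["class"]]
        centers.append(Signal(vals, record_id=row["record_id"], label=label))
        cls_idx.append(row["class"])
        sub_idx.append(row["subclass"])
    bank = KernelBank(centers=centers, class_index=np.array(cls_idx),
                      subclass_index=np.array(sub_idx),
                      class_order=list(payload["class_order"]))
    frbn = FRBNParams(sigma=np.array(payload["sigma"]),
                      shape_a=np.array(payload["shape_a"]),
                      offset_c=np.array(payload["offset_c"]))
    rules = RuleIndex(n_classes=len(payload["class_order"]))
    ts = TSParams(weights=np.array(payload["weights"]),
                  bias=np.array(payload["bias"]))
    return EFRBAINModel(bank=bank, frbn=frbn, rules=rules, ts=ts,
                        class_order=list(payload["class_order"]),
                        dtw_options=payload.get("dtw_options", {}),
                        pooling=payload.get("pooling", "sum"))
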