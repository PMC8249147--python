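"""Synthetic multichannel signal datasets with class/subclass structure.

The generator emulates the situation the model targets: a small, possibly
imbalanced collection of multichannel records where each class contains
several distinct "subclass" shapes, and individual records differ from
their subclass template by random monotone time warping (shared across
channels, as physiological leads share a time base) plus additive Gaussian
noise.

Templates are sums of seeded random-phase sinusoids with a class-specific
baseline offset.  A separation contract is enforced and rechecked by Monte
Carlo: the minimum inter-template DTW distance must exceed
``template_separation`` times the largest observed DTW distance between a
template and its own perturbed records; template drawing is retried a
bounded number of times otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dtw import dtw_distance
from .errors import GeneratorError, ValidationError
from .signal import Signal, SignalDataset

__all__ = ["GeneratorSpec", "GeneratedDataset", "make_templates",
           "sample_record", "generate", "largest_remainder_counts"]

_SEPARATION_PROBES = 5
_MAX_ATTEMPTS = 20


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a modest three-class problem with two shape modes per
    class, 64-timepoint, 3-channel records, mild warping (up to 10% of
    timepoints edited) and noise at 10% of the unit template amplitude —
    separable but not trivial.
    """

    K: int = 3
    subclasses_per_class: Sequence[int] = (2, 2, 2)
    n_channels: int = 3
    base_length: int = 64
    warp_strength: float = 0.1
    noise_sd: float = 0.1
    class_proportions: Optional[Sequence[float]] = None
    n_total: int = 300
    template_separation: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.subclasses_per_class = tuple(int(m) for m in self.subclasses_per_class)
        if self.K < 1 or len(self.subclasses_per_class) != self.K:
            raise ValidationError("need one subclass count per class")
        if any(m < 1 for m in self.subclasses_per_class):
            raise ValidationError("subclass counts must be >= 1")
        if self.warp_strength < 0 or self.noise_sd < 0:
            raise ValidationError("warp strength and noise sd must be >= 0")
        if self.template_separation <= 0:
            raise ValidationError("template separation must be positive")
        if self.base_length < 4 or self.n_channels < 1:
            raise ValidationError("base_length >= 4 and n_channels >= 1 required")
        if self.class_proportions is None:
            self.class_proportions = tuple(1.0 / self.K for _ in range(self.K))
        else:
            self.class_proportions = tuple(float(p) for p in self.class_proportions)
            if len(self.class_proportions) != self.K:
                raise ValidationError("need one proportion per class")
            if any(p < 0 for p in self.class_proportions):
                raise ValidationError("proportions must be nonnegative")
            if abs(sum(self.class_proportions) - 1.0) > 1e-6:
                raise ValidationError("class proportions must sum to 1")

    @property
    def m_total(self) -> int:
        return int(sum(self.subclasses_per_class))

    @property
    def class_labels(self) -> List[str]:
        return [f"C{k + 1}" for k in range(self.K)]


@dataclass
class GeneratedDataset:
    """A dataset plus its generating truth (class, subclass, template id)."""

    dataset: SignalDataset
    truth: pd.DataFrame
    templates: list = field(default_factory=list)


def _draw_template(spec: GeneratorSpec, k: int, rng: np.random.Generator) -> np.ndarray:
    """One smooth (n_channels, base_length) template: three random-phase
    sinusoids per channel plus a class-specific baseline offset."""
    t = np.linspace(0.0, 1.0, spec.base_length)
    vals = np.empty((spec.n_channels, spec.base_length))
    offset = 2.0 * k  # keeps classes apart even under heavy warping
    for ch in range(spec.n_channels):
        x = np.full(spec.base_length, offset)
        for _ in range(3):
            amp = rng.uniform(0.5, 1.5)
            freq = rng.uniform(1.0, 4.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x = x + amp * np.sin(2.0 * np.pi * freq * t + phase)
        vals[ch] = x
    return vals


def sample_record(
    template: Signal,
    warp_strength: float,
    noise_sd: float,
    rng: np.random.Generator,
    record_id: str = "",
) -> Signal:
    """Perturb a template: a random monotone time warp (duplicate/delete up
    to ``warp_strength`` of the timepoints, identical across channels) then
    i.i.d. Gaussian noise."""
    vals = template.values
    T = vals.shape[1]
    idx = list(range(T))
    n_edits = int(np.floor(warp_strength * T))
    n_edits = int(rng.integers(0, n_edits + 1)) if n_edits > 0 else 0
    for _ in range(n_edits):
        if len(idx) > 2 and rng.random() < 0.5:
            del idx[int(rng.integers(0, len(idx)))]
        else:
            pos = int(rng.integers(0, len(idx)))
            idx.insert(pos, idx[pos])
    warped = vals[:, idx]
    if noise_sd > 0:
        warped = warped + rng.normal(0.0, noise_sd, size=warped.shape)
    return Signal(warped, record_id=record_id, label=template.label)


def make_templates(spec: GeneratorSpec) -> List[Signal]:
    """Draw the sum(m_k) subclass templates, enforcing the separation
    contract; deterministic under the spec seed."""
    rng = np.random.default_rng(spec.seed)
    labels = spec.class_labels
    for attempt in range(_MAX_ATTEMPTS):
        templates: List[Signal] = []
        for k in range(spec.K):
            for l in range(spec.subclasses_per_class[k]):
                vals = _draw_template(spec, k, rng)
                templates.append(Signal(vals, record_id=f"T_{k + 1}_{l + 1}",
                                        label=labels[k]))
        # Monte-Carlo estimate of the intra-template perturbation scale
        max_intra = 0.0
        for tpl in templates:
            for _ in range(_SEPARATION_PROBES):
                rec = sample_record(tpl, spec.warp_strength, spec.noise_sd, rng)
                d = dtw_distance(rec, tpl, return_path=False).distance
                max_intra = max(max_intra, d)
        min_inter = np.inf
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                d = dtw_distance(templates[i], templates[j],
                                 return_path=False).distance
                min_inter = min(min_inter, d)
        if len(templates) == 1 or min_inter >= spec.template_separation * max_intra:
            return templates
    raise GeneratorError(
        "could not draw templates satisfying the separation contract "
        f"(need min inter-template DTW >= {spec.template_separation} x the "
        "perturbation scale); lower noise_sd/warp_strength or the "
        "separation requirement"
    )


def largest_remainder_counts(proportions: Sequence[float], total: int) -> np.ndarray:
    """Integer class counts by largest-remainder rounding (exact total,
    deterministic; remainder ties go to the earlier class)."""
    props = np.asarray(proportions, dtype=float)
    exact = props * total
    counts = np.floor(exact).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate(spec: GeneratorSpec) -> GeneratedDataset:
    """Generate ``n_total`` records: class counts by largest-remainder
    rounding of the proportions, subclass templates used round-robin within
    each class."""
    if spec.n_total < spec.K:
        raise ValidationError("n_total must be at least the class count")
    templates = make_templates(spec)
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(2 ** 31))
    counts = largest_remainder_counts(spec.class_proportions, spec.n_total)
    by_class: List[List[Signal]] = [[] for _ in range(spec.K)]
    for tpl, k, l in zip(templates,
                         [k for k in range(spec.K)
                          for _ in range(spec.subclasses_per_class[k])],
                         [l for k in range(spec.K)
                          for l in range(spec.subclasses_per_class[k])]):
        by_class[k].append(tpl)
    signals: List[Signal] = []
    rows = []
    rid = 0
    for k in range(spec.K):
        tpls = by_class[k]
        for i in range(counts[k]):
            l = i % len(tpls)
            record_id = f"r{rid:05d}"
            signals.append(sample_record(tpls[l], spec.warp_strength,
                                         spec.noise_sd, rng, record_id=record_id))
            rows.append({"record_id": record_id,
                         "class": spec.class_labels[k],
                         "subclass": l,
                         "template_id": tpls[l].record_id})
            rid += 1
    dataset = SignalDataset(signals, classes=spec.class_labels)
    truth = pd.DataFrame(rows)
    return GeneratedDataset(dataset=dataset, truth=truth, templates=templates)
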