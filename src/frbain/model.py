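"""High-level modelling interface.

:class:`EFRBAINClassifier` is constructed from a labeled
:class:`~frbain.signal.SignalDataset`; :meth:`~EFRBAINClassifier.fit` runs
the full pipeline — per-class DTW distance matrices, dynamic fuzzy
c-medoids clustering with validity-index model selection, network assembly
around the resulting kernel bank, and gradient training — and returns an
:class:`EFRBAINResults` carrying the trained network, the training history
and evaluation/prediction methods.

    >>> gen = generate(GeneratorSpec(seed=0))
    >>> model = EFRBAINClassifier(gen.dataset, c_range=(2, 4), seed=0)
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .clustering import KernelBank, build_kernel_bank
from .errors import ValidationError
from .network import EFRBAINModel, build_model, save_model
from .signal import SignalDataset
from .training import (MetricsReport, TrainingConfig, TrainingHistory,
                       evaluate, precompute_distances, predict_dataset, train)

__all__ = ["EFRBAINClassifier", "EFRBAINResults"]


class EFRBAINClassifier:
    """E-FRBAIN classification model for a labeled signal dataset.

    Parameters
    ----------
    dataset : SignalDataset
        Labeled training records (at least two classes).
    alpha : float
        Coupling weight of the cluster validity index GD(c) =
        alpha*Cd + (1-alpha)/Sd.
    fuzzifier : float
        Fuzzy clustering exponent (> 1).
    c_range : (int, int) or mapping label -> (int, int)
        Scanned subclass-count range per class; ``(c, c)`` forces a count.
    pooling : {'sum', 'max'}
        Pattern-layer pooling; training requires 'sum'.
    dtw_normalize, band
        Options forwarded to every DTW evaluation.
    seed : int
        Seed for clustering restarts and head initialisation.
    """

    def __init__(
        self,
        dataset: SignalDataset,
        alpha: float = 0.8,
        fuzzifier: float = 2.0,
        c_range: Union[Tuple[int, int], Dict[object, Tuple[int, int]]] = (2, 6),
        restarts: int = 5,
        pooling: str = "sum",
        dtw_normalize: bool = False,
        band: Optional[int] = None,
        seed: int = 0,
    ) -> None:
        if len(dataset) == 0:
            raise ValidationError("empty dataset")
        if dataset.n_classes < 2:
            raise ValidationError("need at least two classes")
        self.dataset = dataset
        self.alpha = alpha
        self.fuzzifier = fuzzifier
        self.c_range = c_range
        self.restarts = restarts
        self.pooling = pooling
        self.dtw_options = {"normalize": dtw_normalize, "band": band}
        self.seed = seed

    def build_bank(self) -> KernelBank:
        """Cluster each class and return its kernel bank."""
        return build_kernel_bank(
            self.dataset, alpha=self.alpha, fuzzifier=self.fuzzifier,
            c_ranges=self.c_range, seed=self.seed, restarts=self.restarts,
            dtw_normalize=self.dtw_options["normalize"],
            band=self.dtw_options["band"],
        )

    def fit(self, config: Optional[TrainingConfig] = None,
            **config_kwargs) -> "EFRBAINResults":
        """Run clustering, assembly and training; returns the results."""
        if config is None:
            config = TrainingConfig(**config_kwargs)
        elif config_kwargs:
            raise ValidationError("pass either a config or keyword overrides")
        bank = self.build_bank()
        network = build_model(bank, seed=self.seed,
                              dtw_options=self.dtw_options,
                              pooling=self.pooling)
        distances = precompute_distances(self.dataset, network)
        trained, history = train(network, self.dataset, config,
                                 distances=distances)
        return EFRBAINResults(model=self, network=trained, history=history,
                              config=config)


@dataclass
class EFRBAINResults:
    """Fitted E-FRBAIN: trained network, history, prediction and metrics."""

    model: EFRBAINClassifier
    network: EFRBAINModel
    history: TrainingHistory
    config: TrainingConfig

    def predict(self, dataset: SignalDataset) -> pd.DataFrame:
        """Predicted label and class probabilities per record."""
        preds = predict_dataset(self.network, dataset)
        rows = []
        for sig, p in zip(dataset, preds):
            row = {"record_id": sig.record_id, "label": p.label}
            for k, cls in enumerate(self.network.class_order):
                row[f"p_{cls}"] = p.class_scores[k]
            rows.append(row)
        return pd.DataFrame(rows)

    def evaluate(self, dataset: SignalDataset) -> MetricsReport:
        return evaluate(self.network, dataset)

    def save(self, path: str) -> str:
        return save_model(self.network, path)

    def summary(self) -> str:
        """Structure and training summary table."""
        net = self.network
        counts = net.bank.per_class_counts
        lines = [
            "E-FRBAIN classification model",
            "=" * 46,
            f"classes (K):            {net.n_classes}",
            f"kernel centers (m):     {net.m}",
            "subclasses per class:   "
            + ", ".join(f"{c}={n}" for c, n in zip(net.class_order, counts)),
            f"rule nodes (K^K):       {net.L}",
            f"pooling:                {net.pooling}",
            f"epochs run:             {self.history.n_epochs}",
            f"final training loss:    {self.history.loss[-1]:.6f}",
            f"stop reason:            {self.history.stop_reason}",
            f"final learning rate:    {self.history.lr[-1]:.4g}",
            "=" * 46,
        ]
        return "\n".join(lines)
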