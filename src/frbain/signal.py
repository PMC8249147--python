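"""Containers and I/O for multichannel time-varying signal records.

A :class:`Signal` is one record: an ``(n_channels, n_timepoints)`` array with
an optional class label.  A :class:`SignalDataset` is an ordered collection of
records sharing a channel count; record lengths may differ because dynamic
time warping is defined for unequal lengths.

On disk a dataset is a directory of plain delimited numeric tables (one per
record, rows are timepoints, columns are channels) plus a manifest CSV with
columns ``record_id,file,label``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataIOError, DimensionError, ParseError, ValidationError

__all__ = ["Signal", "SignalDataset", "load_dataset", "save_dataset"]


@dataclass
class Signal:
    """One multichannel record.

    Parameters
    ----------
    values : ndarray of shape (n_channels, n_timepoints)
        Sample values in arbitrary units.
    record_id : str
        Stable identifier used in manifests and error messages.
    label : str or None
        Class label; ``None`` for unlabeled records.
    channel_names : list of str, optional
        Human-readable channel names (e.g. ECG lead names).
    """

    values: np.ndarray
    record_id: str = ""
    label: Optional[str] = None
    channel_names: Optional[list] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"signal {self.record_id!r}: values must be 2-D "
                f"(channels x timepoints), got shape {self.values.shape}"
            )
        if self.n_channels < 1 or self.n_timepoints < 2:
            raise ValidationError(
                f"signal {self.record_id!r}: need >=1 channel and >=2 "
                f"timepoints, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                f"signal {self.record_id!r}: non-finite values present"
            )
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValidationError(
                f"signal {self.record_id!r}: {len(self.channel_names)} channel "
                f"names for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class SignalDataset:
    """An ordered collection of signals with a consistent channel count.

    ``classes`` lists the distinct labels in first-appearance order; it
    defines the stable class-index mapping used throughout the model.
    """

    signals: list = field(default_factory=list)
    classes: Optional[list] = None

    def __post_init__(self) -> None:
        self.signals = list(self.signals)
        if self.signals:
            n_ch = self.signals[0].n_channels
            for s in self.signals:
                if s.n_channels != n_ch:
                    raise ValidationError(
                        f"inconsistent channel count: record {s.record_id!r} "
                        f"has {s.n_channels} channels, expected {n_ch}"
                    )
        seen = [s.label for s in self.signals if s.label is not None]
        observed = list(dict.fromkeys(seen))
        if self.classes is None:
            self.classes = observed
        else:
            self.classes = list(self.classes)
            unknown = [lab for lab in observed if lab not in self.classes]
            if unknown:
                raise ValidationError(f"labels {unknown} not in declared classes")

    def __len__(self) -> int:
        return len(self.signals)

    def __iter__(self) -> Iterator[Signal]:
        return iter(self.signals)

    def __getitem__(self, i: int) -> Signal:
        return self.signals[i]

    @property
    def n_channels(self) -> int:
        if not self.signals:
            raise ValidationError("empty dataset has no channel count")
        return self.signals[0].n_channels

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def labels(self) -> list:
        return [s.label for s in self.signals]

    def class_indices(self) -> np.ndarray:
        """Integer class index per signal (first-appearance order)."""
        lut = {lab: k for k, lab in enumerate(self.classes)}
        try:
            return np.array([lut[s.label] for s in self.signals], dtype=int)
        except KeyError:
            raise ValidationError("dataset contains unlabeled records")

    def subset(self, indices: Sequence[int]) -> "SignalDataset":
        return SignalDataset([self.signals[i] for i in indices], classes=self.classes)


def _delimiter_for(path: str) -> str:
    return "\t" if path.endswith((".tsv", ".tab")) else ","


def read_record(path: str, record_id: str = "") -> np.ndarray:
    """Read one record file into a (channels, timepoints) array.

    Rows are timepoints and columns are channels; a single header row is
    tolerated and skipped if it is not numeric.
    """
    if not os.path.isfile(path):
        raise DataIOError(f"record {record_id!r}: file not found: {path}")
    delim = _delimiter_for(path)
    with open(path) as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"record {record_id!r}: empty file {path}")
    start = 0
    try:
        [float(x) for x in lines[0].split(delim)]
    except ValueError:
        start = 1  # header row
    rows = []
    for r, ln in enumerate(lines[start:], start=start):
        cells = ln.split(delim)
        row = []
        for c, cell in enumerate(cells):
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"record {record_id!r}: non-numeric cell at row {r}, "
                    f"column {c} in {path}: {cell!r}"
                )
        rows.append(row)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"record {record_id!r}: ragged rows in {path}")
    return np.array(rows, dtype=float).T


def load_dataset(manifest_path: str, data_dir: Optional[str] = None) -> SignalDataset:
    """Load a dataset described by a manifest CSV.

    The manifest needs columns ``record_id``, ``file`` and ``label``; file
    paths are resolved against ``data_dir`` (default: the manifest's
    directory).  An empty label cell yields an unlabeled record.
    """
    if not os.path.isfile(manifest_path):
        raise DataIOError(f"manifest not found: {manifest_path}")
    if data_dir is None:
        data_dir = os.path.dirname(os.path.abspath(manifest_path))
    manifest = pd.read_csv(manifest_path, dtype=str)
    for col in ("record_id", "file", "label"):
        if col not in manifest.columns:
            raise ValidationError(f"manifest missing column {col!r}")
    signals = []
    for row in manifest.itertuples(index=False):
        path = os.path.join(data_dir, row.file)
        values = read_record(path, record_id=row.record_id)
        label = None if pd.isna(row.label) or row.label == "" else str(row.label)
        signals.append(Signal(values, record_id=str(row.record_id), label=label))
    return SignalDataset(signals)


def save_dataset(dataset: SignalDataset, out_dir: str) -> str:
    """Write a dataset as record CSVs plus ``manifest.csv``; returns the
    manifest path.  Round trip: ``load_dataset(save_dataset(d))`` preserves
    labels, record order, and values to the written precision (17 digits,
    i.e. exactly)."""
    if len(dataset) == 0:
        raise ValidationError("refusing to save an empty dataset")
    try:
        os.makedirs(out_dir, exist_ok=True)
    except OSError as exc:
        raise DataIOError(f"cannot create output directory {out_dir}: {exc}")
    rows = []
    for i, sig in enumerate(dataset):
        rid = sig.record_id or f"r{i:05d}"
        fname = f"{rid}.csv"
        try:
            np.savetxt(os.path.join(out_dir, fname), sig.values.T,
                       delimiter=",", fmt="%.17g")
        except OSError as exc:
            raise DataIOError(f"cannot write record {rid}: {exc}")
        rows.append({"record_id": rid, "file": fname,
                     "label": "" if sig.label is None else sig.label})
    manifest_path = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
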