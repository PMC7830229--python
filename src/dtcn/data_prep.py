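"""Windowing and mini-batch construction for labelled multichannel time series.

A raw series is turned into a time-delay representation by a first sliding
window (each window becomes one flattened *data vector* carrying the per-class
count of the sample labels inside it), and then into overlapping mini-batches
by a second sliding window over the data-vector sequence.  Instances inside a
mini-batch keep their natural time order; only whole mini-batches are ever
shuffled, so short-term temporal order survives while the long-range label
sequence is shattered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TimeSeriesRecord",
    "WindowSpec",
    "DataVector",
    "MiniBatch",
    "compute_overlap",
    "sliding_window",
    "make_minibatches",
    "shuffle_minibatches",
    "standardize_fold",
]


@dataclass(frozen=True)
class TimeSeriesRecord:
    """A C-channel series of N samples with one integer class label per sample.

    Parameters
    ----------
    values
        Real matrix of shape ``(N, C)``; finite.
    labels
        Integer vector of length N with class ids in ``[0, n_classes)``.
    n_classes
        Number of classes K.
    """

    values: np.ndarray
    labels: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(np.asarray(self.values, dtype=float))
        if values.ndim == 1:
            values = values[:, None]
        labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("values must be a non-empty (N, C) matrix")
        if labels.shape[0] != values.shape[0]:
            raise ValueError(
                f"got {labels.shape[0]} labels for {values.shape[0]} samples"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if labels.size and (labels.min() < 0 or labels.max() >= self.n_classes):
            raise ValueError(f"labels must lie in [0, {self.n_classes})")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """First-stage sliding window: length ``w`` samples, stride ``s`` samples.

    ``s < w`` yields overlapping windows; ``s == w`` tiles the series.
    """

    w: int
    s: int

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("window length w must be >= 1")
        if not (1 <= self.s <= self.w):
            raise ValueError("stride s must satisfy 1 <= s <= w")


@dataclass(frozen=True)
class DataVector:
    """One flattened window plus the per-class label counts inside it.

    ``features`` is channel-major: the ``w`` lag observations of channel 0,
    then channel 1, and so on — length ``w * C``.  ``label_counts`` has length
    K and sums to ``w``.  ``t_index`` is the 0-based start sample of the
    window in the source series.
    """

    features: np.ndarray
    label_counts: np.ndarray
    t_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        object.__setattr__(
            self, "label_counts", np.asarray(self.label_counts, dtype=np.int64)
        )


@dataclass(frozen=True)
class MiniBatch:
    """B data vectors consecutive in ``t_index`` with a constant step.

    The natural time order inside the batch is an invariant all downstream
    computation relies on: concatenation sublayers join *consecutive* rows.
    """

    vectors: tuple[DataVector, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vectors", tuple(self.vectors))
        if len(self.vectors) < 1:
            raise ValueError("a mini-batch needs at least one data vector")
        t = self.t_indices
        if len(t) > 1:
            steps = np.diff(t)
            if steps[0] <= 0 or not np.all(steps == steps[0]):
                raise ValueError(
                    "mini-batch vectors must be consecutive in t_index "
                    "with a constant positive step (natural time order)"
                )

    @property
    def size(self) -> int:
        return len(self.vectors)

    @property
    def features(self) -> np.ndarray:
        """Stacked feature matrix, shape ``(B, w*C)``."""
        return np.stack([v.features for v in self.vectors])

    @property
    def label_counts(self) -> np.ndarray:
        """Stacked per-class counts, shape ``(B, K)``."""
        return np.stack([v.label_counts for v in self.vectors])

    @property
    def t_indices(self) -> np.ndarray:
        return np.asarray([v.t_index for v in self.vectors], dtype=np.int64)

    def with_features(self, features: np.ndarray) -> "MiniBatch":
        """Return a copy of the batch with ``features`` rows substituted."""
        features = np.asarray(features, dtype=float)
        if features.shape[0] != self.size:
            raise ValueError("feature row count must match batch size")
        return MiniBatch(
            tuple(
                DataVector(features[i], v.label_counts, v.t_index)
                for i, v in enumerate(self.vectors)
            )
        )


def compute_overlap(spec: WindowSpec) -> float:
    """Percentage overlap between neighbouring windows: ``(w - s) / w * 100``."""
    if spec.w == 0:
        raise ValueError("invalid window spec: w must be positive")
    return (spec.w - spec.s) / spec.w * 100.0


def sliding_window(
    record: TimeSeriesRecord, spec: WindowSpec
) -> list[DataVector]:
    """Cut the series into overlapping windows, one :class:`DataVector` each.

    Window ``i`` covers samples ``[i*s, i*s + w)`` (0-based, half-open) and
    there are ``floor((N - w)/s) + 1`` of them; windows that would run past
    the end of the series are dropped.  Each vector's ``label_counts`` tallies
    the per-sample labels inside its window — no majority vote is taken here;
    voting is deferred to the final classifier.
    """
    N, C = record.values.shape
    w, s = spec.w, spec.s
    if N < w:
        raise ValueError(
            f"series too short for windowing: N={N} samples < window length w={w}"
        )
    starts = np.arange(0, N - w + 1, s)
    # (N - w + 1, C, w) view: windows[i, c, t] = values[i + t, c]
    windows = sliding_window_view(record.values, w, axis=0)
    onehot = np.zeros((N, record.n_classes), dtype=np.int64)
    onehot[np.arange(N), record.labels] = 1
    cum = np.vstack([np.zeros((1, record.n_classes), dtype=np.int64), onehot.cumsum(0)])
    out = []
    for start in starts:
        feats = windows[start].reshape(C * w)  # channel-major flattening
        counts = cum[start + w] - cum[start]
        out.append(DataVector(feats.copy(), counts, int(start)))
    return out


def make_minibatches(
    vectors: Sequence[DataVector],
    B: int,
    batch_stride: int | None = None,
) -> list[MiniBatch]:
    """Second-stage sliding window over the data-vector sequence.

    Mini-batch ``j`` holds vectors ``[j*batch_stride, j*batch_stride + B)`` in
    natural time order; ``floor((V - B)/batch_stride) + 1`` batches result.
    ``batch_stride`` defaults to ``B // 2`` (50 % mini-batch overlap),
    mirroring the window-level overlap typically used at the input stage.
    """
    V = len(vectors)
    if batch_stride is None:
        batch_stride = max(1, B // 2)
    if B < 1:
        raise ValueError("mini-batch size B must be >= 1")
    if not (1 <= batch_stride <= B):
        raise ValueError("batch_stride must satisfy 1 <= batch_stride <= B")
    if V < B:
        raise ValueError(f"too few data vectors ({V}) for mini-batch size {B}")
    starts = range(0, V - B + 1, batch_stride)
    return [MiniBatch(tuple(vectors[j : j + B])) for j in starts]


def shuffle_minibatches(
    batches: Sequence[MiniBatch], seed: int
) -> list[MiniBatch]:
    """Permute whole mini-batches; each batch's internal order is untouched.

    Shuffling at the batch level shatters the long-range label sequence (which
    a classifier would otherwise memorise) while preserving the short-term
    temporal order concatenation depends on.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(batches))
    return [batches[i] for i in order]


def standardize_fold(
    train: Sequence[MiniBatch], apply_to: Sequence[MiniBatch]
) -> tuple[list[MiniBatch], list[MiniBatch]]:
    """Z-score both sets using per-feature statistics of the training set only.

    Constant features (zero standard deviation on the training set) are passed
    through unchanged.  Returns ``(train_standardized, apply_standardized)``.
    """
    if len(train) == 0:
        raise ValueError("training batch set must be non-empty")
    X = np.vstack([b.features for b in train])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd == 0.0
    divisor = np.where(keep, 1.0, sd)
    shift = np.where(keep, 0.0, mean)

    def _apply(batches: Iterable[MiniBatch]) -> list[MiniBatch]:
        return [b.with_features((b.features - shift) / divisor) for b in batches]

    return _apply(train), _apply(apply_to)
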