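"""Readers and writers: CSV / ARFF series files and YAML experiment configs.

The delimited-text layout is one row per sample: C numeric channel columns
followed by one integer label column.  Arbitrary label alphabets are remapped
to contiguous class ids ``0..K-1`` in sorted order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.io import arff as scipy_arff

from .data_prep import TimeSeriesRecord, WindowSpec
from .network import TrainConfig
from .rbm import PretrainConfig

__all__ = ["read_csv", "write_csv", "read_arff", "load_config", "configs_from_dict"]


def _to_record(values: np.ndarray, raw_labels: np.ndarray) -> TimeSeriesRecord:
    classes, labels = np.unique(raw_labels, return_inverse=True)
    return TimeSeriesRecord(values, labels, n_classes=len(classes))


def read_csv(path: str | Path, delimiter: str = ",") -> TimeSeriesRecord:
    """Read a labelled series from delimited text (header row optional).

    The last column is the per-sample label; all preceding columns are
    numeric channels.
    """
    first = pd.read_csv(path, sep=delimiter, header=None, nrows=1)
    has_header = not all(
        isinstance(v, (int, float, np.integer, np.floating))
        for v in first.iloc[0]
    )
    df = pd.read_csv(path, sep=delimiter, header=0 if has_header else None)
    if df.shape[1] < 2:
        raise ValueError("need at least one channel column and one label column")
    values = df.iloc[:, :-1].to_numpy(dtype=float)
    return _to_record(values, df.iloc[:, -1].to_numpy())


def write_csv(record: TimeSeriesRecord, path: str | Path,
              delimiter: str = ",") -> None:
    """Write a record as channel columns plus a final integer label column."""
    C = record.n_channels
    df = pd.DataFrame(record.values, columns=[f"ch{c}" for c in range(C)])
    df["label"] = record.labels
    df.to_csv(path, sep=delimiter, index=False)


def read_arff(path: str | Path) -> TimeSeriesRecord:
    """Read a UCI-style ARFF file: numeric attributes plus a nominal class.

    The class attribute is taken to be the last one; nominal values are
    remapped to contiguous integer ids in sorted order.
    """
    data, meta = scipy_arff.loadarff(str(path))
    names = list(meta.names())
    if len(names) < 2:
        raise ValueError("need at least one channel attribute and one class attribute")
    channel_names, class_name = names[:-1], names[-1]
    values = np.column_stack(
        [np.asarray(data[n], dtype=float) for n in channel_names]
    )
    raw = data[class_name]
    if raw.dtype.kind == "S":
        raw = np.char.decode(raw.astype("S"), "utf-8")
    return _to_record(values, raw)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML experiment configuration as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration file must contain a YAML mapping")
    return cfg


def configs_from_dict(
    cfg: dict[str, Any],
) -> tuple[WindowSpec, dict[str, Any], TrainConfig, PretrainConfig | None]:
    """Translate a config mapping into the package's typed configuration objects.

    Recognised keys (all optional except ``window``): ``window.w``,
    ``window.s``, ``batch.size``, ``batch.stride``, ``net.hidden``, ``net.ts``,
    ``train.lr/epochs/momentum``, ``pretrain.enabled/epochs/lr/k``, ``seed``.
    Returns the window spec, a dict of batching/architecture settings, the
    fine-tuning config and the pretraining config (None when disabled).
    """
    window = cfg.get("window", {})
    wspec = WindowSpec(int(window.get("w", 16)), int(window.get("s", 8)))
    batch = cfg.get("batch", {})
    net = cfg.get("net", {})
    seed = int(cfg.get("seed", 0))
    settings = {
        "batch_size": int(batch.get("size", 18)),
        "batch_stride": (int(batch["stride"]) if "stride" in batch else None),
        "hidden": tuple(int(h) for h in net.get("hidden", (20, 20, 20))),
        "ts": int(net.get("ts", 1)),
        "seed": seed,
    }
    train = cfg.get("train", {})
    train_config = TrainConfig(
        learning_rate=float(train.get("lr", 0.2)),
        epochs=int(train.get("epochs", 30)),
        momentum=float(train.get("momentum", 0.0)),
        seed=seed,
    )
    pre = cfg.get("pretrain", {})
    pretrain_config = None
    if pre.get("enabled", False):
        pretrain_config = PretrainConfig(
            epochs=int(pre.get("epochs", 5)),
            learning_rate=float(pre.get("lr", 0.05)),
            k=int(pre.get("k", 1)),
            seed=seed,
        )
    return wspec, settings, train_config, pretrain_config
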