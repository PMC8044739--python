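"""Windowed feature extraction from multichannel wearable recordings.

A recording is a set of synchronized real-valued channels sampled at a
common rate (700 Hz for the chest device this package targets: ECG, EDA,
EMG, respiration, skin temperature and 3-axis acceleration) plus a
per-sample integer task label.  Features are four summary statistics
(mean, SD, min, max) of each channel over non-overlapping 30-second
windows, cut so that no window straddles two task segments.  The result
is a :class:`FeatureTable` — one row per window with subject id, class
label and a 32-dimensional feature vector — which is the unit of all
downstream training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fedaffect")

#: Canonical chest-device channel order; feature columns are channel-major.
CHANNELS: tuple[str, ...] = (
    "ecg", "eda", "emg", "resp", "temp", "acc_x", "acc_y", "acc_z",
)

#: Default summary statistics, in output order.
STATISTICS: tuple[str, ...] = ("mean", "sd", "min", "max")

#: Raw task label -> class index.  Task labels follow the WESAD convention:
#: 0 = transient/unused, 1 = baseline (neutral), 2 = stress, 3 = amusement.
LABEL_TO_CLASS: dict[int, int] = {1: 0, 2: 1, 3: 2}

CLASS_NAMES: tuple[str, ...] = ("neutral", "stress", "amusement")


class SchemaError(ValueError):
    """A required channel or column is missing or misnamed."""


class IntegrityError(ValueError):
    """Channel/label sequences disagree in length or content."""


class FormatError(ValueError):
    """A feature-table file does not match the documented layout."""


class EmptyInputError(ValueError):
    """An operation received an empty sequence."""


@dataclass
class SignalRecord:
    """One subject's synchronized raw channels plus per-sample task labels."""

    subject_id: str
    channels: dict[str, np.ndarray]
    labels: np.ndarray
    sampling_rate_hz: float = 700.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise SchemaError(f"missing channel(s): {', '.join(missing)}")
        # normalize to canonical order and float arrays
        self.channels = {
            name: np.asarray(self.channels[name], dtype=float) for name in CHANNELS
        }
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.labels)
        for name, values in self.channels.items():
            if len(values) != n:
                raise IntegrityError(
                    f"channel '{name}' has {len(values)} samples but "
                    f"label sequence has {n}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.labels)


@dataclass
class WindowingConfig:
    """How windows are cut and summarized."""

    window_seconds: float = 30.0
    statistics: tuple[str, ...] = STATISTICS
    keep_labels: frozenset[int] = frozenset(LABEL_TO_CLASS)

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        unknown = set(self.statistics) - set(_STAT_FUNCS)
        if unknown:
            raise ValueError(f"unknown statistic(s): {sorted(unknown)}")

    def samples_per_window(self, rate_hz: float) -> int:
        n = int(self.window_seconds * rate_hz)
        if n < 1:
            raise ValueError("window shorter than one sample at this rate")
        return n


def feature_names(
    channels: Sequence[str] = CHANNELS, statistics: Sequence[str] = STATISTICS
) -> list[str]:
    """Channel-major feature column names, e.g. ecg_mean, ecg_sd, ..."""
    return [f"{ch}_{st}" for ch in channels for st in statistics]


@dataclass
class FeatureTable:
    """Windowed feature rows: the unit of all training.

    Backed by a DataFrame with columns ``subject_id``, ``label``
    (class index 0/1/2 = neutral/stress/amusement), ``window_index``
    (within (subject, class) temporal order) and one column per feature.
    """

    df: pd.DataFrame
    feature_cols: list[str] = field(default_factory=feature_names)

    META_COLS = ("subject_id", "label", "window_index")

    def __post_init__(self) -> None:
        for col in self.META_COLS:
            if col not in self.df.columns:
                raise FormatError(f"feature table missing column '{col}'")
        missing = [c for c in self.feature_cols if c not in self.df.columns]
        if missing:
            raise FormatError(f"feature table missing feature column(s) {missing}")
        bad = set(self.df["label"].unique()) - {0, 1, 2}
        if bad:
            raise IntegrityError(f"class labels outside {{0,1,2}}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        if self.feature_cols != other.feature_cols:
            return False
        a = self.df[list(self.META_COLS) + self.feature_cols].reset_index(drop=True)
        b = other.df[list(self.META_COLS) + self.feature_cols].reset_index(drop=True)
        if a.shape != b.shape:
            return False
        meta_eq = a[list(self.META_COLS)].astype(str).equals(
            b[list(self.META_COLS)].astype(str)
        )
        feat_close = np.allclose(
            a[self.feature_cols].to_numpy(float),
            b[self.feature_cols].to_numpy(float),
            rtol=1e-12, atol=1e-12,
        )
        return bool(meta_eq and feat_close)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject_id"].astype(str)))

    @property
    def n_features(self) -> int:
        return len(self.feature_cols)

    def features(self) -> np.ndarray:
        return self.df[self.feature_cols].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    def subject_ids(self) -> np.ndarray:
        return self.df["subject_id"].astype(str).to_numpy()

    def per_user(self) -> dict[str, "FeatureTable"]:
        """Split into per-subject tables (order of first appearance)."""
        return {
            sid: FeatureTable(
                self.df[self.df["subject_id"].astype(str) == sid].reset_index(drop=True),
                list(self.feature_cols),
            )
            for sid in self.subjects
        }


# ----------------------------------------------------------------------
# reading raw channel exports
# ----------------------------------------------------------------------

def read_signal_record(
    source,
    subject_id: str = "S0",
    sampling_rate_hz: float = 700.0,
    schema: Mapping[str, str] | None = None,
) -> SignalRecord:
    """Read a delimited channel export into a :class:`SignalRecord`.

    The export has one column per channel plus a ``label`` column; the
    sampling rate is declared by the caller (sidecar convention).
    ``schema`` optionally maps canonical channel names to the column
    names used in the file.

    Raises :class:`SchemaError` for a missing channel column and
    :class:`IntegrityError` for unequal column lengths (pandas pads short
    trailing columns with NaN; any NaN in a required column is treated as
    a length mismatch).
    """
    df = pd.read_csv(source)
    colmap = {name: (schema or {}).get(name, name) for name in CHANNELS}
    missing = [name for name, col in colmap.items() if col not in df.columns]
    if missing:
        raise SchemaError(f"missing channel(s): {', '.join(missing)}")
    label_col = (schema or {}).get("label", "label")
    if label_col not in df.columns:
        raise SchemaError("missing label column")
    used = [colmap[name] for name in CHANNELS] + [label_col]
    if df[used].isna().any().any():
        raise IntegrityError("columns have unequal lengths (NaN padding found)")
    channels = {name: df[colmap[name]].to_numpy(dtype=float) for name in CHANNELS}
    labels = df[label_col].to_numpy(dtype=int)
    return SignalRecord(subject_id, channels, labels, sampling_rate_hz)


# ----------------------------------------------------------------------
# windowing
# ----------------------------------------------------------------------

def segment_label_runs(labels: Sequence[int]) -> list[tuple[int, int, int]]:
    """Maximal runs of identical labels as (label, start, end_exclusive).

    Runs are contiguous, non-overlapping, cover the whole sequence and
    preserve order, so a window cut within one run can never straddle
    two tasks.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise EmptyInputError("empty label sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]


_STAT_FUNCS = {
    "mean": np.mean,
    "sd": lambda v, ddof=0: np.std(v, ddof=ddof),
    "min": np.min,
    "max": np.max,
}


def window_stats(
    values: Sequence[float],
    statistics: Sequence[str] = STATISTICS,
    sd_ddof: int = 0,
) -> np.ndarray:
    """Summary statistics of one window, in the configured order.

    SD uses the population form (divisor n) by default; pass
    ``sd_ddof=1`` for the sample form.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyInputError("empty window")
    out = []
    for st in statistics:
        if st == "sd":
            out.append(_STAT_FUNCS["sd"](values, ddof=sd_ddof))
        else:
            out.append(_STAT_FUNCS[st](values))
    return np.asarray(out, dtype=float)


def extract_features(
    record: SignalRecord,
    cfg: WindowingConfig | None = None,
    sd_ddof: int = 0,
) -> FeatureTable:
    """Cut label-homogeneous windows and summarize every channel.

    For each maximal label run whose label is retained, consecutive
    non-overlapping windows of ``window_seconds`` are cut from the run
    start; a trailing partial window is dropped.  Each window yields one
    row with ``n_channels * n_statistics`` features ordered channel-major.
    Window indices count windows per (subject, class) in temporal order.
    """
    cfg = cfg or WindowingConfig()
    w = cfg.samples_per_window(record.sampling_rate_hz)
    cols = feature_names(CHANNELS, cfg.statistics)
    rows: list[list] = []
    window_counter: dict[int, int] = {}
    for raw_label, start, end in segment_label_runs(record.labels):
        if raw_label not in cfg.keep_labels:
            continue
        cls = LABEL_TO_CLASS[raw_label]
        n_windows = (end - start) // w
        for k in range(n_windows):
            lo = start + k * w
            feats = np.concatenate([
                window_stats(record.channels[ch][lo:lo + w], cfg.statistics, sd_ddof)
                for ch in CHANNELS
            ])
            idx = window_counter.get(cls, 0)
            window_counter[cls] = idx + 1
            rows.append([record.subject_id, cls, idx, *feats])
    if not rows:
        logger.warning(
            "no retained task labels in record %s; empty feature table",
            record.subject_id,
        )
    df = pd.DataFrame(rows, columns=["subject_id", "label", "window_index", *cols])
    if df.empty:
        df = df.astype({"label": int, "window_index": int})
    return FeatureTable(df, cols)


# ----------------------------------------------------------------------
# feature-table I/O
# ----------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    """Write as UTF-8 CSV: subject_id,label,window_index,<feature columns>."""
    cols = list(FeatureTable.META_COLS) + table.feature_cols
    table.df[cols].to_csv(path, index=False)


def read_feature_table(path, feature_cols: list[str] | None = None) -> FeatureTable:
    """Read a feature-table CSV written by :func:`write_feature_table`.

    Raises :class:`FormatError` when the header lacks the meta columns or
    the feature column set does not match the expected 32-column layout
    (or the explicit ``feature_cols`` given).
    """
    df = pd.read_csv(path)
    for col in FeatureTable.META_COLS:
        if col not in df.columns:
            raise FormatError(f"missing column '{col}' in {path}")
    found = [c for c in df.columns if c not in FeatureTable.META_COLS]
    expected = feature_cols if feature_cols is not None else feature_names()
    if found != list(expected):
        raise FormatError(
            f"feature columns {found[:4]}...({len(found)}) do not match the "
            f"expected {len(expected)}-column layout"
        )
    df["subject_id"] = df["subject_id"].astype(str)
    return FeatureTable(df, list(expected))
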