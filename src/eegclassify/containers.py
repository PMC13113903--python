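"""Core in-memory containers shared across the pipeline.

A :class:`Recording` is one subject's continuous multichannel signal; an
:class:`EpochSet` is its segmentation into fixed-length windows; a
:class:`FeatureMatrix` is the epochs-by-features table that selection and
classification operate on.  All amplitudes are in microvolts (µV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Recording", "EpochSet", "FeatureMatrix"]

CONTROL = "control"
PATIENT = "patient"
LABELS = (CONTROL, PATIENT)


@dataclass
class Recording:
    """One subject's continuous multichannel EEG signal.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    label : str
        Class label, ``"control"`` or ``"patient"``.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Channel labels, one per data row (10–20 montage names in practice).
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    """

    subject_id: str
    label: str
    fs: float
    channel_names: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(),
                       channel_names=list(self.channel_names))


@dataclass
class EpochSet:
    """Fixed-length windows cut from one or more recordings.

    ``data`` has shape (n_epochs, n_channels, n_samples); ``subject_ids`` and
    ``labels`` align with the first axis so every epoch carries its subject's
    identity and class — the bookkeeping that leakage-aware validation needs.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_ids: list[str]
    labels: list[str]
    epoch_len: float
    overlap: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        n = self.data.shape[0]
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids/labels must align with epochs")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel dimension does not match channel_names")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.fs, list(self.channel_names),
                        list(self.subject_ids), list(self.labels),
                        self.epoch_len, self.overlap)

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        """Stack epoch sets from several recordings of one cohort."""
        parts = [p for p in parts if p.n_epochs > 0]
        if not parts:
            raise ValueError("no non-empty epoch sets to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.fs != first.fs or p.channel_names != first.channel_names:
                raise ValueError("epoch sets are not compatible")
        return EpochSet(
            np.concatenate([p.data for p in parts], axis=0),
            first.fs, list(first.channel_names),
            [s for p in parts for s in p.subject_ids],
            [l for p in parts for l in p.labels],
            first.epoch_len, first.overlap,
        )


@dataclass
class FeatureMatrix:
    """Epochs-by-features table with per-epoch subject and label maps.

    Feature names use the ``CHANNEL__FEATURE`` convention (e.g.
    ``Fp1__hjorth_mobility``) and are unique.
    """

    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names does not match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        n = self.values.shape[0]
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids/labels must align with rows")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def y(self, positive: str = PATIENT) -> np.ndarray:
        """Binary label vector (1 = positive class, default patient)."""
        return np.asarray([1 if l == positive else 0 for l in self.labels])

    def select(self, names: list[str]) -> "FeatureMatrix":
        """Column subset, in the given order."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], list(names),
                             list(self.subject_ids), list(self.labels))

    def rows(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(self.values[idx], list(self.feature_names),
                             [self.subject_ids[i] for i in idx],
                             [self.labels[i] for i in idx])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", self.labels)
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = ["subject_id", "label"]
        names = [c for c in df.columns if c not in meta]
        return FeatureMatrix(df[names].to_numpy(float), names,
                             df["subject_id"].astype(str).tolist(),
                             df["label"].astype(str).tolist())
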