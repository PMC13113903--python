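"""Dataset readers, writers, filtering and epoch segmentation.

Supports the two source layouts the framework targets — EDF files (19-channel
250 Hz style) and plain-text files with sequentially concatenated channels
(16-channel 128 Hz style) — plus a cohort manifest (``subject_id,label,path``
CSV) that carries the class labels neither signal format stores reliably.

Preprocessing: zero-phase 4th-order Butterworth bandpass (0.5–50 Hz default),
segmentation into overlapping epochs (6 s windows, 2 s overlap default), and
optional per-epoch per-channel z-scoring.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal

from .containers import EpochSet, Recording
from .edf import EDFFormatError, read_edf, write_edf

__all__ = [
    "read_edf", "write_edf", "EDFFormatError",
    "read_concat_text", "write_concat_text",
    "bandpass", "segment", "zscore_epochs", "segment_cohort",
    "write_manifest", "read_manifest", "load_cohort", "save_cohort",
    "n_epochs_expected",
]


class TextFormatError(ValueError):
    """Raised for malformed concatenated-text recordings."""


def read_concat_text(path, n_channels: int, fs: float,
                     channel_names: list[str] | None = None,
                     subject_id: str | None = None,
                     label: str = "unknown") -> Recording:
    """Read a recording stored as sequentially concatenated channels.

    The file holds one value per line: all samples of channel 1, then all of
    channel 2, and so on.  The total value count must divide evenly by
    ``n_channels``.
    """
    path = Path(path)
    try:
        values = np.loadtxt(path, dtype=float, ndmin=1)
    except ValueError as exc:
        raise TextFormatError(f"non-numeric content in {path}: {exc}") from exc
    if values.ndim != 1:
        raise TextFormatError(f"{path} must contain one value per line")
    if values.size == 0 or values.size % n_channels != 0:
        raise TextFormatError(
            f"{path}: {values.size} values not divisible by "
            f"{n_channels} channels")
    data = values.reshape(n_channels, -1)
    if channel_names is None:
        channel_names = [f"Ch{i+1}" for i in range(n_channels)]
    return Recording(subject_id or path.stem, label, fs,
                     list(channel_names), data)


def write_concat_text(rec: Recording, path) -> None:
    """Write channels sequentially, one value per line (lossless text)."""
    np.savetxt(path, rec.data.reshape(-1), fmt="%.10g")


def bandpass(rec: Recording, lo: float = 0.5, hi: float = 50.0,
             order: int = 5) -> Recording:
    """Zero-phase Butterworth bandpass, applied per channel.

    Forward–backward (``sosfiltfilt``) filtering preserves phase; the
    effective magnitude response is the squared single-pass response.  The
    default order 5 keeps mains-frequency content (60 Hz at fs 250) below
    10% power after the two passes.
    """
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= rec.fs / 2:
        raise ValueError(f"hi={hi} must be below Nyquist ({rec.fs / 2})")
    sos = scipy.signal.butter(order, [lo, hi], btype="band", fs=rec.fs,
                              output="sos")
    out = rec.copy()
    out.data = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    return out


def n_epochs_expected(n_samples: int, fs: float, epoch_len: float,
                      overlap: float) -> int:
    """Closed-form epoch count: floor((N - L)/S) + 1, 0 if N < L."""
    L = int(round(epoch_len * fs))
    S = int(round((epoch_len - overlap) * fs))
    if n_samples < L:
        return 0
    return (n_samples - L) // S + 1


def segment(rec: Recording, epoch_len: float = 6.0,
            overlap: float = 2.0) -> EpochSet:
    """Cut a recording into overlapping epochs.

    Windows are ``round(epoch_len * fs)`` samples with hop
    ``round((epoch_len - overlap) * fs)``; 0-based half-open sample
    intervals; a trailing partial window is dropped.  A recording shorter
    than one window yields an empty EpochSet with a warning.
    """
    if not (epoch_len > overlap >= 0):
        raise ValueError("need epoch_len > overlap >= 0")
    L = int(round(epoch_len * rec.fs))
    S = int(round((epoch_len - overlap) * rec.fs))
    n = rec.n_samples
    if n < L:
        warnings.warn(
            f"recording {rec.subject_id} shorter than one epoch "
            f"({n} < {L} samples); returning empty EpochSet")
        data = np.empty((0, rec.n_channels, L))
        return EpochSet(data, rec.fs, list(rec.channel_names), [], [],
                        epoch_len, overlap)
    n_ep = (n - L) // S + 1
    idx = np.arange(L)[None, :] + S * np.arange(n_ep)[:, None]
    data = rec.data[:, idx].transpose(1, 0, 2)  # (n_ep, n_ch, L)
    return EpochSet(data, rec.fs, list(rec.channel_names),
                    [rec.subject_id] * n_ep, [rec.label] * n_ep,
                    epoch_len, overlap)


def segment_cohort(recs: list[Recording], epoch_len: float = 6.0,
                   overlap: float = 2.0) -> EpochSet:
    """Segment every recording and stack the epochs."""
    return EpochSet.concatenate(
        [segment(r, epoch_len, overlap) for r in recs])


def zscore_epochs(ep: EpochSet) -> EpochSet:
    """Per-epoch, per-channel standardization to mean 0, SD 1.

    Channels with zero variance within an epoch are left unchanged (the
    documented degenerate rule); the operation is idempotent.
    """
    out = ep.copy()
    mean = out.data.mean(axis=-1, keepdims=True)
    sd = out.data.std(axis=-1, keepdims=True)
    ok = sd[..., 0] > 0
    centered = out.data - mean
    out.data = np.where(ok[..., None], centered / np.where(sd > 0, sd, 1.0),
                        ep.data)
    return out


# ---------------------------------------------------------------------------
# cohort manifests

def write_manifest(rows: list[tuple[str, str, str]], path) -> None:
    """Write a ``subject_id,label,path`` manifest CSV."""
    pd.DataFrame(rows, columns=["subject_id", "label", "path"]).to_csv(
        path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"subject_id", "label", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} missing columns "
                         f"{sorted(required - set(df.columns))}")
    return df


def save_cohort(recs: list[Recording], out_dir, fmt: str = "edf",
                fs_text_channels: int | None = None) -> Path:
    """Write one file per recording plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recs:
        if fmt == "edf":
            p = out_dir / f"{rec.subject_id}.edf"
            write_edf(rec, p)
        elif fmt == "text":
            p = out_dir / f"{rec.subject_id}.txt"
            write_concat_text(rec, p)
        else:
            raise ValueError(f"unknown cohort format {fmt!r}")
        rows.append((rec.subject_id, rec.label, p.name))
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest


def load_cohort(manifest_path, fmt: str = "auto", n_channels: int | None = None,
                fs: float | None = None,
                channel_names: list[str] | None = None) -> list[Recording]:
    """Load every recording listed in a manifest.

    ``fmt='auto'`` dispatches on file extension (.edf vs text).  Text files
    need ``n_channels`` and ``fs`` since the format stores neither.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    recs = []
    for _, row in df.iterrows():
        p = base / row["path"]
        ext = p.suffix.lower()
        use_edf = fmt == "edf" or (fmt == "auto" and ext == ".edf")
        if use_edf:
            rec = read_edf(p, subject_id=row["subject_id"],
                           label=row["label"])
        else:
            if n_channels is None or fs is None:
                raise ValueError(
                    "text cohorts require n_channels and fs")
            rec = read_concat_text(p, n_channels, fs,
                                   channel_names=channel_names,
                                   subject_id=row["subject_id"],
                                   label=row["label"])
        recs.append(rec)
    return recs
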