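"""EDF (European Data Format) reading and writing.

Reading delegates to MNE's native EDF reader and converts amplitudes back to
µV.  Writing is a minimal EDF(+)-compatible 16-bit writer sufficient for
round-tripping synthetic cohorts: one data record per second, all channels at
a common sampling rate, physical dimension µV.  Quantization error is bounded
by half the physical range divided by 2^16 - 2.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np

from .containers import Recording

__all__ = ["read_edf", "write_edf", "edf_quantization_step"]


class EDFFormatError(ValueError):
    """Raised for unreadable or unsupported EDF files."""


def read_edf(path, subject_id: str | None = None,
             label: str = "unknown") -> Recording:
    """Read an EDF file into a :class:`Recording` (amplitudes in µV).

    Channels come back in file order at the header sampling rate; the
    subject id defaults to the filename stem.  Class labels are not stored
    in EDF headers — supply them via a cohort manifest.
    """
    import mne

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises various types for malformed input
        raise EDFFormatError(f"cannot read EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE works in volts
    return Recording(
        subject_id=subject_id or path.stem,
        label=label,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        data=data,
    )


def edf_quantization_step(data: np.ndarray) -> float:
    """Quantization step the writer below introduces for this data."""
    phys_max = max(float(np.max(np.abs(data))), 1e-6) * 1.001
    return 2 * phys_max / (2 ** 16 - 2)


def write_edf(rec: Recording, path) -> None:
    """Write a Recording as a 16-bit EDF file.

    The sampling rate must be a positive integer (one data record per
    second).  Symmetric physical range per file; digital range ±32767.
    """
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_ch = rec.n_channels
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one 1-s data record")
    data = rec.data[:, : n_rec * fs]

    phys_max = max(float(np.max(np.abs(data))), 1e-6) * 1.001
    # format the range into the 8-char header field, then reuse the *parsed*
    # value for scaling so writer and reader agree exactly
    for prec in (6, 5, 4, 3):
        phys_str = f"{phys_max:.{prec}g}"
        if len(phys_str) <= 7:  # leave room for the minus sign on phys_min
            break
    phys_max = float(phys_str)
    dig_max = 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(data * scale), -dig_max, dig_max).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8),
        f(f"X X X {rec.subject_id}", 80),
        f("Startdate 01-JAN-2000 X X X", 80),
        f("01.01.00", 8),
        f("00.00.00", 8),
        f(str(256 * (n_ch + 1)), 8),
        f("", 44),
        f(str(n_rec), 8),
        f("1", 8),
        f(str(n_ch), 4),
    ])
    labels = b"".join(f(ch, 16) for ch in rec.channel_names)
    transducer = b"".join(f("", 80) for _ in range(n_ch))
    phys_dim = b"".join(f("uV", 8) for _ in range(n_ch))
    phys_min = b"".join(f("-" + phys_str, 8) for _ in range(n_ch))
    phys_max_b = b"".join(f(phys_str, 8) for _ in range(n_ch))
    dig_min = b"".join(f(str(-dig_max), 8) for _ in range(n_ch))
    dig_max_b = b"".join(f(str(dig_max), 8) for _ in range(n_ch))
    prefilter = b"".join(f("", 80) for _ in range(n_ch))
    n_samp = b"".join(f(str(fs), 8) for _ in range(n_ch))
    reserved = b"".join(f("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + phys_dim + phys_min
                 + phys_max_b + dig_min + dig_max_b + prefilter + n_samp
                 + reserved)
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())
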