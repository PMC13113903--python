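"""Per-channel time- and frequency-domain EEG features.

Thirteen time-domain descriptors (moments, amplitudes, sum of absolute
differences, Hjorth activity/mobility/complexity) and eight spectral
descriptors (four canonical band powers, normalized spectral entropy, and the
mean/skewness/kurtosis of the Welch PSD) are computed per channel per epoch
and assembled into a :class:`~eegclassify.containers.FeatureMatrix` with
``CHANNEL__FEATURE`` column names.

Canonical band edges: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.stats

from .containers import EpochSet, FeatureMatrix

__all__ = [
    "BandDefinition", "CANONICAL_BANDS", "PSDEstimate",
    "time_features", "welch_psd", "band_power", "spectral_features",
    "build_feature_matrix", "TIME_FEATURE_NAMES", "SPECTRAL_FEATURE_NAMES",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid band edges [{self.lo}, {self.hi})")


CANONICAL_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

TIME_FEATURE_NAMES = (
    "mean", "variance", "std", "ptp", "min", "max", "rms", "sad",
    "skewness", "kurtosis",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
)

SPECTRAL_FEATURE_NAMES = (
    "band_delta", "band_theta", "band_alpha", "band_beta",
    "spectral_entropy", "psd_mean", "psd_skewness", "psd_kurtosis",
)


@dataclass
class PSDEstimate:
    """One-sided Welch power spectral density estimate.

    ``power`` may carry leading axes (e.g. epochs x channels); the frequency
    grid is always the trailing axis.  ``n_segments`` is the number of
    averaged periodograms, ``seg_len`` the per-segment length in samples.
    """

    freqs: np.ndarray
    power: np.ndarray
    fs: float
    n_segments: int
    seg_len: int


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros(np.broadcast_shapes(np.shape(num), np.shape(den)))
    np.divide(num, den, out=out, where=np.asarray(den) > 0)
    return out


def _hjorth(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Hjorth parameters along the last axis.

    Constant signals get mobility = complexity = 0 by convention so that
    downstream selection never sees NaN.
    """
    var0 = np.var(x, axis=-1)
    dx = np.diff(x, axis=-1)
    var1 = np.var(dx, axis=-1)
    ddx = np.diff(dx, axis=-1)
    var2 = np.var(ddx, axis=-1)
    mobility = np.sqrt(_safe_ratio(var1, var0))
    mob_dx = np.sqrt(_safe_ratio(var2, var1))
    complexity = _safe_ratio(mob_dx, mobility)
    return var0, mobility, complexity


def time_features(x: np.ndarray) -> dict[str, float]:
    """Thirteen time-domain features of a single-channel epoch.

    Includes the sum of absolute successive differences (SAD), RMS amplitude,
    distribution shape (Fisher skewness, excess kurtosis) and the three
    Hjorth parameters.  Requires at least 3 samples (second difference).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("time_features requires a 1-D signal of length >= 3")
    vals = _time_features_block(x[None, :])[0]
    return dict(zip(TIME_FEATURE_NAMES, vals))


def _time_features_block(x: np.ndarray) -> np.ndarray:
    """Time features for a stack of signals; trailing axis is time."""
    var0, mobility, complexity = _hjorth(x)
    std = np.sqrt(var0)
    # constant signals have zero skewness/kurtosis by the same degenerate rule
    import warnings as _warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        skew = scipy.stats.skew(x, axis=-1)
        kurt = scipy.stats.kurtosis(x, axis=-1)  # excess (Fisher)
    skew = np.where(var0 > 0, skew, 0.0)
    kurt = np.where(var0 > 0, kurt, 0.0)
    cols = [
        np.mean(x, axis=-1),
        var0,
        std,
        np.ptp(x, axis=-1),
        np.min(x, axis=-1),
        np.max(x, axis=-1),
        np.sqrt(np.mean(x ** 2, axis=-1)),
        np.sum(np.abs(np.diff(x, axis=-1)), axis=-1),
        skew,
        kurt,
        var0,
        mobility,
        complexity,
    ]
    return np.stack(cols, axis=-1)


def welch_psd(x: np.ndarray, fs: float, seg_len: int | None = None,
              overlap_frac: float = 0.5, window: str = "hann") -> PSDEstimate:
    """Welch PSD: averaged windowed periodograms, one-sided density scaling.

    Defaults give 1-s Hann segments with 50% overlap (>= 5 averaged segments
    on a 6-s epoch, 1 Hz resolution).  ``x`` may be multi-dimensional; the
    trailing axis is time.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if seg_len is None:
        seg_len = min(int(fs), n)
    if seg_len > n:
        raise ValueError("seg_len exceeds signal length")
    if not (0 <= overlap_frac < 1):
        raise ValueError("overlap_frac must be in [0, 1)")
    noverlap = int(seg_len * overlap_frac)
    freqs, power = scipy.signal.welch(
        x, fs=fs, window=window, nperseg=seg_len, noverlap=noverlap,
        detrend="constant", scaling="density", axis=-1)
    hop = seg_len - noverlap
    n_segments = (n - seg_len) // hop + 1
    return PSDEstimate(freqs, power, fs, n_segments, seg_len)


def band_power(psd: PSDEstimate, band: BandDefinition) -> float | np.ndarray:
    """Trapezoidal integral of the PSD over [lo, hi), in µV²."""
    if band.lo < psd.freqs[0] - 1e-9 or band.hi > psd.freqs[-1] + 1e-9:
        raise ValueError(
            f"band [{band.lo}, {band.hi}) outside PSD grid "
            f"[{psd.freqs[0]}, {psd.freqs[-1]}]")
    mask = (psd.freqs >= band.lo) & (psd.freqs <= band.hi)
    if mask.sum() < 2:
        return np.zeros(psd.power.shape[:-1]) if psd.power.ndim > 1 else 0.0
    return np.trapezoid(psd.power[..., mask], psd.freqs[mask], axis=-1)


def spectral_features(psd: PSDEstimate, bands=CANONICAL_BANDS,
                      entropy_lo: float = 0.5,
                      entropy_hi: float = 50.0) -> dict[str, float]:
    """Band powers plus entropy and PSD moments for a single-channel PSD.

    Spectral entropy is the Shannon entropy (base 2) of the PSD normalized to
    sum 1 over the 0.5–50 Hz grid, divided by log2 of the bin count, so it
    lies in [0, 1]: 0 for a single concentrated line, 1 for a flat spectrum.
    Zero total power maps to entropy 0 by convention.
    """
    if psd.power.ndim != 1:
        raise ValueError("spectral_features expects a single-channel PSD")
    vals = _spectral_features_block(psd, bands, entropy_lo, entropy_hi)
    names = [f"band_{b.name}" for b in bands] + [
        "spectral_entropy", "psd_mean", "psd_skewness", "psd_kurtosis"]
    return dict(zip(names, vals))


def _spectral_features_block(psd: PSDEstimate, bands,
                             entropy_lo: float = 0.5,
                             entropy_hi: float = 50.0) -> np.ndarray:
    """Spectral features for PSDs with arbitrary leading axes."""
    cols = [band_power(psd, b) for b in bands]
    hi = min(entropy_hi, psd.fs / 2)
    mask = (psd.freqs >= entropy_lo) & (psd.freqs <= hi)
    p = psd.power[..., mask]
    total = p.sum(axis=-1, keepdims=True)
    q = _safe_ratio(p, total)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(q > 0, q * np.log2(q), 0.0)
    n_bins = mask.sum()
    entropy = -plogp.sum(axis=-1) / np.log2(n_bins)
    entropy = np.where(total[..., 0] > 0, entropy, 0.0)

    var_p = np.var(p, axis=-1)
    import warnings as _warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        sk = scipy.stats.skew(p, axis=-1)
        ku = scipy.stats.kurtosis(p, axis=-1)
    cols += [
        entropy,
        np.mean(p, axis=-1),
        np.where(var_p > 0, sk, 0.0),
        np.where(var_p > 0, ku, 0.0),
    ]
    return np.stack(cols, axis=-1)


def build_feature_matrix(ep: EpochSet, bands=CANONICAL_BANDS,
                         seg_len: int | None = None,
                         overlap_frac: float = 0.5,
                         window: str = "hann") -> FeatureMatrix:
    """Extract all 21 per-channel features for every epoch.

    With C channels the matrix has 21·C columns named ``CHANNEL__FEATURE``;
    column order is channel-major and deterministic.  Subject ids and labels
    are carried through from the EpochSet.
    """
    if ep.n_epochs == 0:
        raise ValueError("cannot extract features from an empty EpochSet")
    tf = _time_features_block(ep.data)              # (n_ep, n_ch, 13)
    psd = welch_psd(ep.data, ep.fs, seg_len=seg_len,
                    overlap_frac=overlap_frac, window=window)
    sf = _spectral_features_block(psd, bands)       # (n_ep, n_ch, 8)
    block = np.concatenate([tf, sf], axis=-1)       # (n_ep, n_ch, 21)
    n_ep = ep.n_epochs
    values = block.reshape(n_ep, -1)
    feat_names = list(TIME_FEATURE_NAMES) + [f"band_{b.name}" for b in bands] + [
        "spectral_entropy", "psd_mean", "psd_skewness", "psd_kurtosis"]
    names = [f"{ch}__{f}" for ch in ep.channel_names for f in feat_names]
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        e, c = bad[0]
        raise FloatingPointError(
            f"non-finite feature at epoch {e}, column {names[c]}")
    return FeatureMatrix(values, names, list(ep.subject_ids), list(ep.labels))
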