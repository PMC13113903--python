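"""Synthetic two-class EEG cohort generator.

Emulates resting-state cohorts of the kind used in schizophrenia EEG studies:
multichannel band-limited oscillations riding on 1/f^k background noise, with
class-dependent band-power effects (reduced alpha and elevated theta in the
patient class), a log-normal per-subject gain shared across bands and
channels, and injectable ocular (blink) and muscle (EMG) artifacts.

Oscillations are narrowband-filtered Gaussian noise rather than pure sines so
that spectra are realistically broad.  The per-subject gain is the single
knob that makes epochs from one subject correlated — the structure that lets
epoch-level k-fold validation leak subject identity.

No physiological forward modelling is attempted: channels are statistically
exchangeable apart from the frontal targeting of blinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .containers import CONTROL, PATIENT, Recording
from .features import CANONICAL_BANDS

__all__ = ["SynthParams", "gen_recording", "gen_cohort", "inject_artifacts",
           "DATASET2_CHANNELS", "DATASET1_CHANNELS"]

# 10-20 montage names of the two public-dataset layouts this generator mimics
DATASET1_CHANNELS = ["Fp2", "F8", "T4", "T6", "O2", "Fp1", "F7", "T3", "T5",
                     "O1", "F4", "C4", "P4", "F3", "C3", "P3", "Fz", "Cz", "Pz"]
DATASET2_CHANNELS = ["F7", "F3", "F4", "F8", "T3", "C3", "Cz", "C4", "T4",
                     "T5", "P3", "Pz", "P4", "T6", "O1", "O2"]

_BAND_EDGES = {b.name: (b.lo, b.hi) for b in CANONICAL_BANDS}


@dataclass
class SynthParams:
    """Cohort-level generation parameters.

    Amplitudes are RMS µV per band oscillation; ``patient_multipliers``
    scale the patient class's band amplitudes (alpha < 1, theta > 1 by
    default, mirroring the reduced-alpha / elevated-theta resting-state
    pattern).  ``subject_effect_sd`` is the SD of the per-subject log-normal
    gain applied to all oscillations.  ``noise_amplitude`` is the RMS of the
    1/f^``noise_exponent`` background.  Rates are events per minute.
    """

    n_control: int = 14
    n_patient: int = 14
    fs: float = 128.0
    duration: float = 60.0
    n_channels: int = 16
    channel_names: list[str] = field(
        default_factory=lambda: list(DATASET2_CHANNELS))
    band_amplitudes: dict[str, float] = field(default_factory=lambda: {
        "delta": 15.0, "theta": 10.0, "alpha": 20.0, "beta": 5.0})
    patient_multipliers: dict[str, float] = field(default_factory=lambda: {
        "delta": 1.0, "theta": 1.3, "alpha": 0.7, "beta": 1.0})
    subject_effect_sd: float = 0.3
    noise_exponent: float = 1.0
    noise_amplitude: float = 8.0
    blink_rate: float = 0.0
    emg_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.n_channels != len(self.channel_names):
            # regenerate generic names when the count is customised
            if self.channel_names == DATASET2_CHANNELS:
                self.channel_names = [f"Ch{i+1}" for i in range(self.n_channels)]
            else:
                raise ValueError("channel_names length must equal n_channels")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be >= 0")
        if any(m < 0 for m in self.patient_multipliers.values()):
            raise ValueError("patient multipliers must be >= 0")
        if self.blink_rate < 0 or self.emg_rate < 0:
            raise ValueError("artifact rates must be >= 0")
        if self.subject_effect_sd < 0 or self.noise_amplitude < 0:
            raise ValueError("subject_effect_sd/noise_amplitude must be >= 0")


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    hi = min(hi, 0.99 * fs / 2)
    sos = scipy.signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    # pad so filter transients do not bias the kept span
    pad = int(2 * fs)
    x = scipy.signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _one_over_f_noise(rng: np.random.Generator, n: int,
                      exponent: float) -> np.ndarray:
    """Unit-RMS noise with power spectrum ~ 1/f^exponent (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity; DC is zeroed below anyway
    spec = spec / f ** (exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x ** 2))


def gen_recording(params: SynthParams, subject_id: str, label: str,
                  seed: int, subject_gain: float = 1.0) -> Recording:
    """Generate one subject's recording.

    Per channel the signal is the sum over bands of
    ``amplitude * class_multiplier * subject_gain * narrowband_noise`` plus
    the 1/f^k background.  Deterministic for a fixed seed.
    """
    if label not in (CONTROL, PATIENT):
        raise ValueError(f"label must be '{CONTROL}' or '{PATIENT}'")
    n = int(round(params.duration * params.fs))
    rng = np.random.default_rng(seed)
    data = np.empty((params.n_channels, n))
    for c in range(params.n_channels):
        x = np.zeros(n)
        for band, amp in params.band_amplitudes.items():
            mult = (params.patient_multipliers.get(band, 1.0)
                    if label == PATIENT else 1.0)
            a = amp * mult * subject_gain
            lo, hi = _BAND_EDGES[band]
            osc = _narrowband_noise(rng, n, params.fs, lo, hi)
            x += a * osc
        x += params.noise_amplitude * _one_over_f_noise(
            rng, n, params.noise_exponent)
        data[c] = x
    rec = Recording(subject_id, label, params.fs,
                    list(params.channel_names), data)
    if params.blink_rate > 0 or params.emg_rate > 0:
        rec = inject_artifacts(rec, params.blink_rate, params.emg_rate,
                               seed=seed + 1)
    return rec


def gen_cohort(params: SynthParams) -> list[Recording]:
    """Generate the full two-class cohort.

    Subject gains are drawn once per subject (log-normal, SD
    ``subject_effect_sd`` on the log scale); per-subject seeds derive from
    ``params.seed`` so the whole cohort is reproducible bit-for-bit.
    """
    n_total = params.n_control + params.n_patient
    if n_total < 2:
        raise ValueError("cohort needs at least 2 subjects in total")
    rng = np.random.default_rng(params.seed)
    recs: list[Recording] = []
    specs = ([(f"C{i+1:03d}", CONTROL) for i in range(params.n_control)]
             + [(f"P{i+1:03d}", PATIENT) for i in range(params.n_patient)])
    for sid, label in specs:
        gain = float(np.exp(rng.normal(0.0, params.subject_effect_sd)))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        recs.append(gen_recording(params, sid, label, sub_seed,
                                  subject_gain=gain))
    return recs


def _is_frontal(name: str) -> bool:
    return name.startswith("Fp") or name.startswith("F")


def inject_artifacts(rec: Recording, blink_rate: float, emg_rate: float,
                     seed: int) -> Recording:
    """Return a copy of ``rec`` with ocular and muscle artifacts added.

    Blinks: smooth ~100 µV Gaussian transients (sigma 0.15 s) whose energy
    sits below 5 Hz, applied to frontal channels (10–20 names starting with
    "Fp"/"F").  EMG: 0.25 s Hann-windowed bursts of >20 Hz noise on all
    channels.  Event times are Poisson with the given per-minute rates.  The
    input recording is left unchanged.
    """
    if blink_rate < 0 or emg_rate < 0:
        raise ValueError("artifact rates must be >= 0")
    out = rec.copy()
    if blink_rate == 0 and emg_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    n, fs = rec.n_samples, rec.fs
    t_total_min = rec.duration / 60.0
    frontal = [i for i, ch in enumerate(rec.channel_names) if _is_frontal(ch)]
    if not frontal:
        frontal = list(range(rec.n_channels))

    n_blinks = rng.poisson(blink_rate * t_total_min)
    sigma = 0.15  # seconds; spectral content concentrated well below 5 Hz
    half = int(4 * sigma * fs)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / (sigma * fs)) ** 2)
    for _ in range(n_blinks):
        center = int(rng.uniform(half, n - half - 1))
        amp = 100.0 * rng.uniform(0.8, 1.2)
        for c in frontal:
            scale = rng.uniform(0.7, 1.0)
            out.data[c, center - half:center + half + 1] += amp * scale * kernel

    n_emg = rng.poisson(emg_rate * t_total_min)
    burst_len = max(int(0.25 * fs), 8)
    hi_sos = scipy.signal.butter(4, 20.0, btype="high", fs=fs, output="sos")
    win = scipy.signal.windows.hann(burst_len)
    for _ in range(n_emg):
        start = int(rng.uniform(0, n - burst_len - 1))
        for c in range(rec.n_channels):
            burst = scipy.signal.sosfilt(hi_sos,
                                         rng.standard_normal(burst_len))
            rms = np.sqrt(np.mean(burst ** 2))
            if rms > 0:
                burst = burst / rms * 30.0 * rng.uniform(0.5, 1.0)
            out.data[c, start:start + burst_len] += win * burst
    return out
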