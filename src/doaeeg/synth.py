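"""Synthetic multi-subject frontal EEG with a known depth -> spectrum -> PSI structure.

The generator stands in for clinical SedLine-style recordings: 4 frontal
channels (L1, L2, R1, R2) sampled at 178.2 Hz, whose band composition
(delta/theta/alpha/beta/gamma) shifts with a latent anesthetic depth
``d(t) in [0, 1]``.  Ground-truth PSI is *defined* as ``round(100 * (1 - d))``,
so the spectral content of a window is sufficient, in principle, to recover
its PSI label.  Contamination adds blink-like ocular artifacts (large, slow,
same polarity on all frontal channels), 50 Hz line noise, and sub-0.5 Hz
baseline drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal
from scipy.interpolate import PchipInterpolator

CHANNEL_NAMES = ("L1", "L2", "R1", "R2")

#: EEG band edges in Hz: delta, theta, alpha, beta, gamma.
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 31.0),
    "gamma": (31.0, 51.0),
}
BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")


def default_band_weights(d: float | np.ndarray) -> np.ndarray:
    """Band-power weights (delta, theta, alpha, beta, gamma) as a function of depth.

    Monotonically shifts power from beta/gamma (awake) toward delta (deep).
    Returned weights are non-negative and not all zero for any d in [0, 1];
    they are normalized internally so only their ratios matter.
    """
    d = np.asarray(d, dtype=float)
    w = np.stack(
        [
            0.10 + 1.8 * d**2,
            0.15 + 0.25 * d,
            0.55 - 0.25 * d,
            0.60 * (1.0 - d) + 0.05,
            0.35 * (1.0 - d) + 0.03,
        ]
    )
    return w


@dataclass
class SimSpec:
    """Parameters of a synthetic acquisition.

    Amplitudes are in microvolts.  ``artifact_amplitude_ratio`` is the blink
    peak expressed as a multiple of the clean-EEG RMS; ``artifact_rate`` is
    blinks per minute.  ``subject_gain_sd`` is the log-SD of a per-subject
    multiplicative amplitude gain (lognormal, median 1).
    """

    n_subjects: int = 1
    duration_per_subject: float = 120.0
    fs: float = 178.2
    band_weight_fn: Callable[[np.ndarray], np.ndarray] = field(
        default=default_band_weights
    )
    artifact_rate: float = 8.0
    artifact_amplitude_ratio: float = 5.0
    line_noise_amplitude: float = 3.0
    drift_amplitude: float = 20.0
    subject_gain_sd: float = 0.25
    eeg_rms: float = 10.0
    background_rms: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")


@dataclass
class DepthTrajectory:
    """Latent anesthetic depth over time and the PSI it defines."""

    times: np.ndarray
    depth: np.ndarray

    @property
    def psi(self) -> np.ndarray:
        return np.clip(np.round(100.0 * (1.0 - self.depth)), 0, 100)

    def depth_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.depth)

    def psi_at(self, t: np.ndarray) -> np.ndarray:
        return np.clip(np.round(100.0 * (1.0 - self.depth_at(t))), 0, 100)


@dataclass
class EEGRecord:
    """Continuous multi-channel EEG in microvolts.

    ``clean`` optionally holds the uncontaminated record and ``components``
    the individually injected contaminant traces, so that artifact-removal
    quality can be measured against ground truth.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str] = CHANNEL_NAMES
    subject_id: str = "S00"
    clean: "EEGRecord | None" = None
    components: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def _subject_rng(spec: SimSpec, subject_idx: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, subject_idx, tag])


def make_trajectory(
    spec: SimSpec, subject_idx: int = 0, dt: float = 0.25
) -> DepthTrajectory:
    """An awake -> induction -> maintenance (with a brief deep dip) ->
    emergence -> light plateau -> recovery depth profile.

    Phase durations and levels are jittered per subject so that, after
    segmentation, awake (AW) windows dominate and deep-anesthesia (DA)
    windows are rarest, mimicking the strong class imbalance of real
    peri-operative recordings.
    """
    rng = _subject_rng(spec, subject_idx, 1)
    T = spec.duration_per_subject
    j = lambda x, s: x * (1.0 + s * (rng.uniform() - 0.5))  # noqa: E731
    base = j(0.62, 0.10)
    dip = min(0.95, base + 0.20)
    # (fraction-of-duration, target depth) knots; Pchip keeps it piecewise smooth.
    knots = [
        (0.0, j(0.05, 0.4)),
        (j(0.28, 0.1), j(0.06, 0.4)),
        (0.34, j(0.35, 0.1)),  # induction passes through LA/NA
        (0.40, base),
        (0.50, j(base, 0.06)),
        (0.56, dip),  # brief DA excursion
        (0.60, dip),
        (0.66, j(base, 0.06)),
        (0.72, base),
        (0.78, j(0.30, 0.15)),  # emergence into a light-anesthesia plateau
        (j(0.88, 0.05), j(0.30, 0.15)),
        (0.94, j(0.08, 0.4)),
        (1.0, j(0.05, 0.4)),
    ]
    t_knots = np.array([k[0] for k in knots]) * T
    d_knots = np.array([k[1] for k in knots])
    times = np.arange(0.0, T + dt, dt)
    depth = PchipInterpolator(t_knots, d_knots)(np.clip(times, 0, T))
    depth = np.clip(depth, 0.0, 1.0)
    return DepthTrajectory(times=times, depth=depth)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, [lo, min(hi, 0.999 * fs / 2)], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f-shaped background restricted to 0.5-60 Hz."""
    white = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    band = (f >= 0.5) & (f <= 60.0)
    shape[band] = 1.0 / np.sqrt(f[band])
    x = np.fft.irfft(white * shape, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_clean_eeg(
    spec: SimSpec, trajectory: DepthTrajectory, subject_idx: int = 0
) -> EEGRecord:
    """Synthesize a clean 4-channel record following the depth trajectory.

    Each channel is a sum of per-band band-limited Gaussian noises whose
    instantaneous variances follow ``band_weight_fn(d(t))`` (normalized to a
    unit sum, so total RMS stays ``eeg_rms`` x subject gain), plus a 1/f
    background of RMS ``background_rms``.
    """
    if trajectory.times[-1] < spec.duration_per_subject - 1e-9:
        raise ValueError("trajectory does not cover duration_per_subject")
    n = int(round(spec.duration_per_subject * spec.fs))
    t = np.arange(n) / spec.fs
    d = trajectory.depth_at(t)
    w = np.asarray(spec.band_weight_fn(d), dtype=float)
    if w.shape[0] != len(BAND_ORDER):
        raise ValueError("band_weight_fn must return 5 weights")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("band weights must be finite and non-negative")
    wsum = w.sum(axis=0)
    rng = _subject_rng(spec, subject_idx, 2)
    gain = float(np.exp(rng.normal(0.0, spec.subject_gain_sd)))
    data = np.zeros((len(CHANNEL_NAMES), n))
    for ch in range(len(CHANNEL_NAMES)):
        x = np.zeros(n)
        if np.any(wsum > 0):
            env = w / np.where(wsum > 0, wsum, 1.0)
            for b, name in enumerate(BAND_ORDER):
                if np.all(env[b] == 0):
                    continue
                lo, hi = BANDS[name]
                x += np.sqrt(env[b]) * _bandlimited_noise(rng, n, spec.fs, lo, hi)
            x *= spec.eeg_rms
        if spec.background_rms > 0:
            x += spec.background_rms * _pink_noise(rng, n, spec.fs)
        data[ch] = gain * x
    return EEGRecord(data=data, fs=spec.fs, subject_id=f"S{subject_idx:02d}")


def _blink_pulse(n: int) -> np.ndarray:
    """Smooth biphasic pulse of n samples with unit peak magnitude.

    A positive main lobe followed by a smaller negative lobe; all spectral
    content sits well below 5 Hz for the 300-500 ms durations used.
    """
    u = np.linspace(0.0, 1.0, n)
    p = np.sin(np.pi * u) ** 2 - 0.35 * np.sin(np.pi * np.clip(2 * u - 1, 0, 1)) ** 2
    return p / np.max(np.abs(p))


#: relative blink projection onto (L1, L2, R1, R2); frontopolar sites see more.
_BLINK_TOPOGRAPHY = np.array([1.0, 0.8, 1.0, 0.8])


def simulate_eoa_train(
    spec: SimSpec, duration: float, subject_idx: int = 0
) -> np.ndarray:
    """Blink-artifact trace (channels x samples) to be added to clean EEG.

    Blink onsets follow a Poisson process at ``artifact_rate`` per minute;
    each blink is a 300-500 ms biphasic pulse of identical polarity on all
    four frontal channels, peak amplitude ``artifact_amplitude_ratio`` x
    ``eeg_rms`` (with 10% per-event jitter).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * spec.fs))
    trace = np.zeros((len(CHANNEL_NAMES), n))
    if spec.artifact_rate <= 0 or spec.artifact_amplitude_ratio == 0:
        return trace
    rng = _subject_rng(spec, subject_idx, 3)
    rate_per_s = spec.artifact_rate / 60.0
    t = 0.0
    amp0 = spec.artifact_amplitude_ratio * spec.eeg_rms
    while True:
        t += rng.exponential(1.0 / rate_per_s)
        if t >= duration:
            break
        width = rng.uniform(0.3, 0.5)
        npulse = int(round(width * spec.fs))
        i0 = int(round(t * spec.fs))
        i1 = min(i0 + npulse, n)
        if i1 <= i0:
            continue
        pulse = amp0 * rng.uniform(0.9, 1.1) * _blink_pulse(npulse)[: i1 - i0]
        trace[:, i0:i1] += _BLINK_TOPOGRAPHY[:, None] * pulse[None, :]
    return trace


def contaminate(clean: EEGRecord, spec: SimSpec, subject_idx: int = 0) -> EEGRecord:
    """Add ocular artifacts, 50 Hz line noise and slow drift to a clean record.

    The returned record keeps ``clean`` and the individual injected traces in
    ``components`` so downstream artifact-removal can be scored against truth.
    """
    n = clean.n_samples
    t = np.arange(n) / clean.fs
    rng = _subject_rng(spec, subject_idx, 4)
    eoa = simulate_eoa_train(spec, clean.duration, subject_idx)[:, :n]
    if eoa.shape[1] < n:
        eoa = np.pad(eoa, ((0, 0), (0, n - eoa.shape[1])))
    line = spec.line_noise_amplitude * np.sin(
        2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
    )
    drift = np.zeros(n)
    if spec.drift_amplitude > 0:
        for f0 in (0.05, 0.11, 0.23):
            drift += np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        drift *= spec.drift_amplitude / max(np.max(np.abs(drift)), 1e-12)
    components = {"eoa": eoa, "line": line, "drift": drift}
    data = clean.data + eoa + line[None, :] + drift[None, :]
    return EEGRecord(
        data=data,
        fs=clean.fs,
        channel_names=clean.channel_names,
        subject_id=clean.subject_id,
        clean=clean,
        components=components,
    )


@dataclass
class SubjectData:
    """One subject's contaminated recording and its ground-truth trajectory."""

    record: EEGRecord
    trajectory: DepthTrajectory


def generate_dataset(spec: SimSpec) -> list[SubjectData]:
    """Simulate ``n_subjects`` recordings, each with its own trajectory.

    Deterministic given ``spec.seed``: every subject's trajectory, EEG and
    contamination derive from independent streams keyed on (seed, subject).
    """
    out = []
    for s in range(spec.n_subjects):
        traj = make_trajectory(spec, s)
        clean = simulate_clean_eeg(spec, traj, s)
        rec = contaminate(clean, spec, s)
        out.append(SubjectData(record=rec, trajectory=traj))
    return out
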