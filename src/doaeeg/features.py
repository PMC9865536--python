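"""Spectral and entropy features used by the conventional DoA regressors.

Fourteen features per 4 s window: three absolute-power totals (all four
frontal channels; left hemisphere L1+L2; right hemisphere R1+R2), five
relative band powers (delta, theta, alpha, beta, gamma on the all-channel
average spectrum), the 95% spectral edge frequency of each hemisphere, and
the sample entropy of each channel.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.signal import windows

from .synth import BANDS, BAND_ORDER

#: fixed column order of the feature vector.
FEATURE_NAMES = (
    "total_power_frontopolar",
    "total_power_left",
    "total_power_right",
    "rel_power_delta",
    "rel_power_theta",
    "rel_power_alpha",
    "rel_power_beta",
    "rel_power_gamma",
    "sef95_left",
    "sef95_right",
    "sampen_L1",
    "sampen_L2",
    "sampen_R1",
    "sampen_R2",
)

TOTAL_BAND = (1.0, 51.0)

#: montage: L1,L2 (FP1,F7) form the left hemisphere; R1,R2 (FP2,F8) the right.
LEFT_CHANNELS = (0, 1)
RIGHT_CHANNELS = (2, 3)


@lru_cache(maxsize=8)
def _dpss_tapers(n: int, nw: float = 2.5, k: int = 4):
    return windows.dpss(n, nw, Kmax=k, return_ratios=False)


def multitaper_psd(x: np.ndarray, fs: float, nw: float = 2.5, k: int = 4):
    """Multitaper PSD estimate of a 1-D signal.

    Averages ``k`` DPSS-tapered periodograms (time-halfbandwidth ``nw``).
    Returns (frequencies, density) on the one-sided grid 0..fs/2; the density
    integrates (trapezoid) to approximately the signal variance.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("multitaper_psd expects a 1-D signal")
    n = x.size
    if n < 64:
        raise ValueError(f"signal too short for PSD estimation ({n} < 64 samples)")
    tapers = _dpss_tapers(n, nw, k)
    # each taper has unit energy, so |FFT|^2 / fs is already a density
    spec = np.fft.rfft(tapers * x[None, :], axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs
    psd[1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, psd


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    m = (freqs >= lo) & (freqs <= hi)
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], freqs[m]))


def band_powers(freqs: np.ndarray, psd: np.ndarray):
    """Absolute and relative powers of the five canonical EEG bands.

    Absolute power is the PSD integral over each band; relative powers are
    each band's share of the total 1-51 Hz power and sum to 1.
    """
    if freqs[-1] < TOTAL_BAND[1]:
        raise ValueError("PSD grid does not cover 1-51 Hz")
    absolute = {
        name: _band_integral(freqs, psd, *BANDS[name]) for name in BAND_ORDER
    }
    total = sum(absolute.values())
    if total <= 0:
        raise ValueError("zero total band power: relative powers undefined")
    relative = {name: absolute[name] / total for name in BAND_ORDER}
    return absolute, relative


def sef95(freqs: np.ndarray, psd: np.ndarray, fraction: float = 0.95) -> float:
    """Spectral edge frequency: smallest f with >=95% of 1-51 Hz power below it."""
    m = (freqs >= TOTAL_BAND[0]) & (freqs <= TOTAL_BAND[1])
    f, p = freqs[m], psd[m]
    if f.size < 2 or np.all(p <= 0):
        raise ValueError("zero power in 1-51 Hz: SEF undefined")
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(f))])
    idx = int(np.searchsorted(cum, fraction * cum[-1]))
    return float(f[min(idx, f.size - 1)])


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) with r = r_factor * std(x).

    -ln(A/B) where B counts pairs of m-length templates within Chebyshev
    distance < r (self-matches excluded) and A the same for length m+1.
    Conventions: a constant series has entropy 0; if no (m+1)-matches exist
    the result is +inf.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series too short for SampEn (n={n}, m={m})")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd
    # Chebyshev distances between m-embeddings, built up one lag at a time.
    nm = n - m  # number of (m+1)-length templates
    d = np.abs(x[:, None] - x[None, :])
    dm = d[: n - m + 1, : n - m + 1].copy()
    for k in range(1, m):
        np.maximum(dm, d[k : k + n - m + 1, k : k + n - m + 1], out=dm)
    close_m = dm < r
    np.fill_diagonal(close_m, False)
    b = int(np.triu(close_m[:nm, :nm], 1).sum())
    dm1 = np.maximum(dm[:nm, :nm], d[m : m + nm, m : m + nm])
    close_m1 = dm1 < r
    np.fill_diagonal(close_m1, False)
    a = int(np.triu(close_m1, 1).sum())
    if b == 0 or a == 0:
        return float("inf")
    return float(-np.log(a / b))


def extract_features(data: np.ndarray, fs: float) -> np.ndarray:
    """The ordered 14-feature vector of a cleaned 4 x n window.

    Powers in uV^2; relative powers dimensionless (sum to 1); SEF95 in Hz
    computed on each hemisphere's average PSD; SampEn per channel.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] != 4:
        raise ValueError("expected 4 x n window")
    psds = []
    for ch in range(4):
        freqs, p = multitaper_psd(data[ch], fs)
        psds.append(p)
    psds = np.asarray(psds)
    totals = [_band_integral(freqs, p, *TOTAL_BAND) for p in psds]
    total_all = float(sum(totals))
    total_left = float(sum(totals[c] for c in LEFT_CHANNELS))
    total_right = float(sum(totals[c] for c in RIGHT_CHANNELS))
    _, rel = band_powers(freqs, psds.mean(axis=0))
    sef_l = sef95(freqs, psds[list(LEFT_CHANNELS)].mean(axis=0))
    sef_r = sef95(freqs, psds[list(RIGHT_CHANNELS)].mean(axis=0))
    ents = [sample_entropy(data[ch]) for ch in range(4)]
    vec = np.array(
        [total_all, total_left, total_right]
        + [rel[name] for name in BAND_ORDER]
        + [sef_l, sef_r]
        + ents
    )
    return vec
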