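"""Empirical-mode decomposition and its complete-ensemble variant (CEEMDAN).

Sifting uses cubic-spline envelopes through local extrema with mirrored
boundary extrema, a Cauchy-type stopping criterion, and a cap on sift
iterations.  The ensemble variant follows the complete-ensemble scheme:
stage k adds the k-th IMF of the *same* noise realizations to the current
residue, and each extracted mode is subtracted exactly, so

    sum(IMFs) + residue == input   (to machine precision, by construction).

Noise-mode tables are cached per (length, ensemble, seed) because the
artifact-removal pipeline decomposes many equal-length wavelet coefficient
arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

_MAX_SIFTS = 8
_SD_STOP = 0.2


def _extrema(x: np.ndarray):
    """Indices of strict local maxima and minima (plateaus take one index)."""
    dx = np.diff(x)
    # collapse zero slopes to the sign of the previous nonzero slope
    s = np.sign(dx)
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    ds = np.diff(s)
    maxima = np.where(ds < 0)[0] + 1
    minima = np.where(ds > 0)[0] + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through x[idx], with 2 mirrored extrema per end."""
    ti, xi = t[idx].astype(float), x[idx]
    n_ext = min(2, idx.size)
    t_pre = 2 * t[0] - ti[n_ext - 1 :: -1]
    x_pre = xi[n_ext - 1 :: -1]
    t_post = 2 * t[-1] - ti[: -n_ext - 1 : -1]
    x_post = xi[: -n_ext - 1 : -1]
    tt = np.concatenate([t_pre, ti, t_post])
    xx = np.concatenate([x_pre, xi, x_post])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    return CubicSpline(tt[keep], xx[keep])(t)


def _sift_one(x: np.ndarray) -> np.ndarray | None:
    """Extract one IMF from x, or None if x has too few extrema."""
    t = np.arange(x.size)
    h = x
    for _ in range(_MAX_SIFTS):
        maxima, minima = _extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return None if h is x else h
        upper = _envelope(h, maxima, t)
        lower = _envelope(h, minima, t)
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = float(np.sum(h**2))
        if denom > 0 and float(np.sum(mean**2)) / denom < _SD_STOP**2:
            return h_new
        h = h_new
    return h


def emd(x: np.ndarray, max_imfs: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Plain EMD: returns (imfs [k x n], residue [n]); sum + residue == x."""
    x = np.asarray(x, dtype=float)
    imfs = []
    r = x.copy()
    while len(imfs) < max_imfs:
        maxima, minima = _extrema(r)
        if maxima.size + minima.size < 4:
            break
        imf = _sift_one(r)
        if imf is None:
            break
        imfs.append(imf)
        r = r - imf
    return (np.array(imfs) if imfs else np.empty((0, x.size))), r


_noise_cache: dict[tuple, np.ndarray] = {}


def _noise_modes(n: int, ensemble: int, max_imfs: int, seed: int) -> np.ndarray:
    """IMF tables E_k(w_i) of unit-variance noise, shape (ensemble, max_imfs, n)."""
    key = (n, ensemble, max_imfs, seed)
    if key not in _noise_cache:
        rng = np.random.default_rng(seed)
        table = np.zeros((ensemble, max_imfs, n))
        for i in range(ensemble):
            w = rng.standard_normal(n)
            modes, _ = emd(w, max_imfs=max_imfs)
            table[i, : modes.shape[0]] = modes
        _noise_cache[key] = table
    return _noise_cache[key]


def ceemdan(
    x: np.ndarray,
    ensemble: int = 50,
    noise_std: float = 0.2,
    max_imfs: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-ensemble EMD with adaptive noise.

    Parameters mirror the usual CEEMDAN knobs: ``ensemble`` trials,
    ``noise_std`` as a fraction of the signal SD, at most ``max_imfs`` modes.
    Deterministic given ``seed``.  Degenerate (constant or near-constant)
    inputs return no IMFs and the input as residue.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("ceemdan expects a 1-D signal")
    if x.size < 16:
        raise ValueError("signal too short for CEEMDAN (need >= 16 samples)")
    sd = float(x.std())
    if sd == 0:
        return np.empty((0, x.size)), x.copy()
    noise = _noise_modes(x.size, ensemble, max_imfs, seed)
    imfs = []
    r = x.copy()
    for k in range(max_imfs):
        maxima, minima = _extrema(r)
        if maxima.size + minima.size < 4:
            break
        eps = noise_std * float(r.std())
        acc = np.zeros(x.size)
        contributed = 0
        for i in range(ensemble):
            w_k = noise[i, k]
            imf = _sift_one(r + eps * w_k)
            if imf is not None:
                acc += imf
                contributed += 1
        if contributed == 0:
            break
        imfs.append(acc / contributed)
        r = r - imfs[-1]
    return (np.array(imfs) if imfs else np.empty((0, x.size))), r
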