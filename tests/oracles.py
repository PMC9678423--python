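"""Independent brute-force reference implementations used by the tests.

These deliberately avoid scipy.signal and the package's own spectral code:
Welch spectra are assembled from explicit DFT sums with hand-written linear
detrending and a periodic Hann window; HRV statistics are direct loops over
the definitions.
"""

from __future__ import annotations

import math

import numpy as np


def brute_welch(x, y, fs: float, n_segments: int = 5):
    """Direct-DFT Welch auto/cross spectra (one-sided density).

    Segment length floor(2N/(K+1)) forced even, 50% overlap, per-segment
    least-squares linear detrend, periodic Hann taper, conj(X)*Y cross
    convention, density normalization by fs * sum(w^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    L = (2 * n) // (n_segments + 1)
    L -= L % 2
    hop = L // 2
    m = np.arange(L)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * m / L)
    design = np.vstack([m, np.ones(L)]).T
    n_freq = L // 2 + 1
    n_seg = (n - L) // hop + 1
    sxx = np.zeros(n_freq)
    syy = np.zeros(n_freq)
    sxy = np.zeros(n_freq, dtype=complex)
    dft = np.exp(-2j * np.pi * np.outer(np.arange(n_freq), m) / L)
    for s in range(n_seg):
        xs = x[s * hop : s * hop + L]
        ys = y[s * hop : s * hop + L]
        xd = xs - design @ np.linalg.lstsq(design, xs, rcond=None)[0]
        yd = ys - design @ np.linalg.lstsq(design, ys, rcond=None)[0]
        X = dft @ (w * xd)
        Y = dft @ (w * yd)
        sxx += np.abs(X) ** 2
        syy += np.abs(Y) ** 2
        sxy += np.conj(X) * Y
    scale = 1.0 / (fs * np.sum(w**2) * n_seg)
    one_sided = np.full(n_freq, 2.0)
    one_sided[0] = 1.0
    if L % 2 == 0:
        one_sided[-1] = 1.0
    freqs = np.arange(n_freq) * fs / L
    return freqs, sxx * scale * one_sided, syy * scale * one_sided, sxy * scale * one_sided


def windowed_detrended_variance(y, fs: float, n_segments: int = 5) -> float:
    """Hann-weighted variance of the linearly detrended Welch segments.

    This is the quantity the integrated one-sided density must reproduce
    (DFT Parseval identity per segment, averaged over segments).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    L = (2 * n) // (n_segments + 1)
    L -= L % 2
    hop = L // 2
    m = np.arange(L)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * m / L)
    design = np.vstack([m, np.ones(L)]).T
    out = []
    for s in range((n - L) // hop + 1):
        seg = y[s * hop : s * hop + L]
        d = seg - design @ np.linalg.lstsq(design, seg, rcond=None)[0]
        out.append(np.sum((w * d) ** 2) / np.sum(w**2))
    return float(np.mean(out))


def brute_rmssd(rr) -> float:
    total = 0.0
    count = 0
    for a, b in zip(rr[:-1], rr[1:]):
        total += (b - a) ** 2
        count += 1
    return math.sqrt(total / count)


def brute_pnn50(rr) -> float:
    hits = 0
    count = 0
    for a, b in zip(rr[:-1], rr[1:]):
        if abs(b - a) > 50.0:
            hits += 1
        count += 1
    return 100.0 * hits / count


def narrowband_delay_pair(fs: float = 4.0, n: int = 1200, gain: float = 8.0,
                          tau_s: float = 1.5, center_hz: float = 0.10,
                          width_hz: float = 0.03, seed: int = 2):
    """Deterministic narrowband input and its exactly delayed, scaled output.

    A cosine comb on the LF bin grid (multiples of 1/segment-length, so the
    delay is circular per Welch segment) with Gaussian amplitude taper
    centered on ``center_hz``; y = gain * x(t - tau).
    """
    t = np.arange(n) / fs
    L = ((2 * n) // 6) - (((2 * n) // 6) % 2)
    df = fs / L
    freqs = np.arange(0.04, 0.15 + df / 2, df)
    amps = np.exp(-((freqs - center_hz) ** 2) / (2 * width_hz**2))
    rng = np.random.default_rng(seed)
    phis = rng.uniform(0, 2 * np.pi, freqs.size)
    x = np.zeros(n)
    y = np.zeros(n)
    for a, f, p in zip(amps, freqs, phis):
        x += a * np.cos(2 * np.pi * f * t + p)
        y += gain * a * np.cos(2 * np.pi * f * (t - tau_s) + p)
    return x, y
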