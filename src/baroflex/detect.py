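"""Beat and breath detection from raw waveforms.

Extracts R-peak times from a lead-II ECG, per-cycle systolic / diastolic /
mean pressure from the continuous arterial waveform, and per-breath
ventilation summaries (Rf, VT, V̇e) from respiratory flow.

The R-peak detector is a minimal Pan–Tompkins-style scheme: band-pass
5–25 Hz, squaring, moving-average envelope, adaptive threshold at half the
rolling 2-s envelope maximum, 250 ms refractory period. It is designed for
clean resting ECG, not for ambulatory or pathological recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigurationError, InsufficientDataError, SignalQualityError

# Detector constants (seconds unless noted)
REFRACTORY_S = 0.25          # minimum physiological R-R spacing enforced
ENVELOPE_WINDOW_S = 0.15     # moving-average width for the QRS energy envelope
ROLLING_MAX_S = 2.0          # span of the adaptive-threshold rolling maximum
THRESHOLD_FRACTION = 0.5     # threshold = fraction x rolling envelope max
QRS_SEARCH_HALFWIDTH_S = 0.06  # raw-signal argmax refinement window
BREATH_LOWPASS_HZ = 1.0      # flow low-pass cutoff before zero-crossing search


@dataclass
class BeatAnnotations:
    """R-peak times (s from recording start) with per-beat confidence."""

    r_times: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.quality is None:
            self.quality = np.ones_like(self.r_times)
        self.quality = np.clip(np.asarray(self.quality, dtype=float), 0.0, 1.0)
        if self.r_times.size > 1 and np.any(np.diff(self.r_times) <= 0):
            raise ValueError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.r_times.size)


@dataclass
class VentilationSummary:
    """Per-recording breathing summary.

    rf : breaths/min; vt_mean : L (tidal volume); ve : L/min (minute
    ventilation, rf x vt_mean); breath_times : onset of each breath, s.
    """

    rf: float
    vt_mean: float
    ve: float
    breath_times: np.ndarray

    def __post_init__(self) -> None:
        self.breath_times = np.asarray(self.breath_times, dtype=float)
        if min(self.rf, self.vt_mean, self.ve) < 0:
            raise ValueError("ventilation summaries must be non-negative")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> BeatAnnotations:
    """Locate R peaks in an ECG trace.

    Parameters
    ----------
    ecg : array of ECG samples (mV), positive R deflection assumed.
    fs : sampling rate, Hz (>= 250 for reliable QRS localization).

    Returns annotations with each R time placed on the sample of maximum
    band-passed (zero-phase) amplitude inside the detected QRS complex —
    identical to the raw maximum for a symmetric QRS, but robust to
    broadband noise. Detections closer than the 0.25 s refractory period to
    the previous accepted beat are dropped.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 250:
        raise ConfigurationError(f"fs={fs} Hz too low for R-peak detection (need >= 250)")
    if ecg.size / fs < 10:
        raise InsufficientDataError("need at least 10 s of ECG for beat detection")
    sd = float(np.std(ecg))
    if not np.isfinite(sd) or sd < 1e-9 * max(1.0, abs(float(np.mean(ecg)))) or sd == 0.0:
        raise SignalQualityError("flat-line ECG: no QRS energy")

    sos = signal.butter(2, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, ecg)
    env = ndimage.uniform_filter1d(band * band, size=max(3, int(ENVELOPE_WINDOW_S * fs)))
    roll_max = ndimage.maximum_filter1d(env, size=max(3, int(ROLLING_MAX_S * fs)))
    thr = THRESHOLD_FRACTION * roll_max

    # contiguous supra-threshold regions -> one candidate each
    idx = np.flatnonzero(env > thr)
    if idx.size == 0:
        raise SignalQualityError("no QRS candidates above adaptive threshold")
    breaks = np.flatnonzero(np.diff(idx) > 1)
    region_starts = np.r_[idx[0], idx[breaks + 1]]
    region_ends = np.r_[idx[breaks], idx[-1]]

    half = int(QRS_SEARCH_HALFWIDTH_S * fs)
    peaks: list[int] = []
    quals: list[float] = []
    refractory_n = REFRACTORY_S * fs
    for a, b in zip(region_starts, region_ends):
        c = a + int(np.argmax(env[a : b + 1]))
        lo, hi = max(0, c - half), min(ecg.size, c + half + 1)
        # localize on the zero-phase band-passed signal: same peak position
        # for a symmetric QRS, far more robust to broadband noise than raw
        p = lo + int(np.argmax(band[lo:hi]))
        if peaks and p - peaks[-1] < refractory_n:
            continue  # refractory suppression: keep the earlier beat
        peaks.append(p)
        quals.append(env[c] / roll_max[c] if roll_max[c] > 0 else 0.0)

    if len(peaks) < 2:
        raise SignalQualityError("fewer than 2 beats detected")
    return BeatAnnotations(r_times=np.asarray(peaks) / fs, quality=np.asarray(quals))


def extract_pressure_beats(
    bp: np.ndarray, fs: float, beats: BeatAnnotations
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-cycle SBP / DBP / MAP from the arterial pressure waveform.

    Each cardiac cycle is the R-to-R window [t_k, t_{k+1}); SBP is the cycle
    maximum, DBP the minimum, and MAP the time average of the waveform over
    the entire cycle (trapezoidal integration divided by cycle length). The
    final, incomplete cycle is dropped, so the returned arrays have
    ``len(beats) - 1`` entries.

    Returns
    -------
    (sbp, dbp, map, valid) — mmHg arrays plus a validity mask; a cycle
    containing non-finite samples is flagged invalid (NaN values).
    """
    bp = np.asarray(bp, dtype=float)
    t = beats.r_times
    if t.size < 2:
        raise InsufficientDataError("need at least 2 beats to form a cardiac cycle")
    n_cycles = t.size - 1
    sbp = np.full(n_cycles, np.nan)
    dbp = np.full(n_cycles, np.nan)
    map_ = np.full(n_cycles, np.nan)
    valid = np.zeros(n_cycles, dtype=bool)
    for k in range(n_cycles):
        i0 = int(round(t[k] * fs))
        i1 = int(round(t[k + 1] * fs))
        i0 = max(0, min(i0, bp.size - 1))
        i1 = max(i0 + 1, min(i1, bp.size - 1))
        seg = bp[i0 : i1 + 1]
        if not np.all(np.isfinite(seg)):
            continue
        sbp[k] = seg.max()
        dbp[k] = seg.min()
        map_[k] = np.trapezoid(seg, dx=1.0 / fs) / ((i1 - i0) / fs)
        valid[k] = True
    return sbp, dbp, map_, valid


def detect_breaths(flow: np.ndarray, fs: float) -> VentilationSummary:
    """Breath-by-breath ventilation from respiratory flow (L/s).

    Breaths are delimited by negative-to-positive zero crossings of the
    1 Hz low-pass-filtered flow. Tidal volume is the integral of positive
    (inspiratory) flow over each breath; Rf is breaths per minute over the
    analyzed span; V̇e = Rf x mean VT.
    """
    flow = np.asarray(flow, dtype=float)
    if flow.size / fs < 30:
        raise InsufficientDataError("need at least 30 s of flow for breath detection")
    if float(np.std(flow)) == 0.0:
        raise SignalQualityError("flat flow signal: no breaths")

    sos = signal.butter(4, BREATH_LOWPASS_HZ, btype="lowpass", fs=fs, output="sos")
    lp = signal.sosfiltfilt(sos, flow)
    neg = lp[:-1] < 0
    pos = lp[1:] >= 0
    xi = np.flatnonzero(neg & pos)
    if xi.size < 2:
        raise SignalQualityError("no negative-to-positive zero crossings in flow")
    # sub-sample crossing times by linear interpolation
    frac = -lp[xi] / (lp[xi + 1] - lp[xi])
    t_cross = (xi + frac) / fs

    vts = []
    dt = 1.0 / fs
    insp = np.clip(flow, 0.0, None)
    for a, b in zip(t_cross[:-1], t_cross[1:]):
        i0, i1 = int(np.ceil(a * fs)), int(np.floor(b * fs))
        if i1 <= i0:
            continue
        vts.append(np.trapezoid(insp[i0 : i1 + 1], dx=dt))
    if not vts:
        raise SignalQualityError("no complete breaths found")
    span_min = (t_cross[-1] - t_cross[0]) / 60.0
    rf = len(vts) / span_min
    vt_mean = float(np.mean(vts))
    return VentilationSummary(rf=rf, vt_mean=vt_mean, ve=rf * vt_mean,
                              breath_times=t_cross[:-1])
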