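"""Aligned RR / SBP beat series, ectopy flagging, equidistant resampling.

The central container is :class:`BeatSeries`: beat times ``t`` (n beats),
and per-cardiac-cycle arrays of length n-1 — ``rr`` (ms, interval opened by
beat k), ``sbp``/``dbp``/``map`` (mmHg, pressures of that same cycle) and a
validity mask. RR and SBP are index-aligned at zero lag by default: rr_k,
the interval from beat k to k+1, pairs with sbp_k, the systole of that
cycle. Each cycle's values are timestamped at the interval onset t_k.

Spectral stages require evenly sampled input, so valid beats are passed
through a natural cubic spline and resampled at 4 Hz, strictly inside the
span of valid beats (no extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .detect import BeatAnnotations
from .errors import ConfigurationError, InsufficientDataError

MIN_BEATS = 30               # hard floor; 5-min recordings are the design target
ARTIFACT_REL_THRESHOLD = 0.30  # fractional RR deviation from rolling median
ARTIFACT_WINDOW_BEATS = 11     # rolling-median window (odd)
MAX_ECTOPIC_FRACTION = 0.05    # above this the session is unsuitable
RESAMPLE_HZ = 4.0


@dataclass
class BeatSeries:
    """Beat-by-beat RR/SBP series (see module docstring for layout)."""

    t: np.ndarray                 # beat times, s; length n
    rr: np.ndarray                # ms; length n-1
    sbp: np.ndarray               # mmHg; length n-1
    dbp: np.ndarray = None        # type: ignore[assignment]
    map: np.ndarray = None        # type: ignore[assignment]
    valid: np.ndarray = None      # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        n = self.t.size
        if self.rr.size != n - 1 or self.sbp.size != n - 1:
            raise ValueError("rr and sbp must have length len(t) - 1")
        for name in ("dbp", "map"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(n - 1, np.nan))
            else:
                setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.valid is None:
            self.valid = np.isfinite(self.rr) & (self.rr > 0)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.size != n - 1:
            raise ValueError("valid mask must have length len(t) - 1")

    def __len__(self) -> int:
        """Number of beats (cycles = len - 1)."""
        return int(self.t.size)

    @property
    def ectopic_fraction(self) -> float:
        """Fraction of cardiac cycles flagged invalid."""
        if self.valid.size == 0:
            return 0.0
        return float(np.mean(~self.valid))

    @property
    def interval_times(self) -> np.ndarray:
        """Timestamp of each cycle = its onset beat time."""
        return self.t[:-1]


@dataclass
class EquidistantSeries:
    """Uniformly resampled track ready for spectral analysis."""

    fs: float                  # Hz
    start_s: float             # time of the first sample
    values: np.ndarray
    source_span_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("equidistant series must be finite everywhere")

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.values.size) / self.fs

    def __len__(self) -> int:
        return int(self.values.size)


def build_beat_series(
    beats: BeatAnnotations,
    sbp: np.ndarray,
    dbp: np.ndarray | None = None,
    map_: np.ndarray | None = None,
    pressure_valid: np.ndarray | None = None,
    lag_beats: int = 0,
) -> BeatSeries:
    """Pair RR intervals with per-cycle pressures.

    ``sbp`` (and optional dbp/map/validity) must be the per-cycle arrays from
    :func:`baroflex.detect.extract_pressure_beats`, i.e. of length
    ``len(beats) - 1``. ``lag_beats`` shifts the pairing: rr_k is paired with
    sbp_{k - lag}; the default 0 pairs each interval with its own systole.
    """
    t = beats.r_times
    if t.size < MIN_BEATS:
        raise InsufficientDataError(
            f"{t.size} beats < hard floor of {MIN_BEATS}; spectral analysis "
            "targets ~5-min recordings"
        )
    rr = np.diff(t) * 1000.0
    n = rr.size

    def _align(arr: np.ndarray | None) -> np.ndarray:
        if arr is None:
            return np.full(n, np.nan)
        arr = np.asarray(arr, dtype=float)
        if arr.size != n:
            raise ValueError("pressure arrays must have length len(beats) - 1")
        if lag_beats == 0:
            return arr
        out = np.full(n, np.nan)
        if lag_beats > 0:
            out[lag_beats:] = arr[:-lag_beats]
        else:
            out[:lag_beats] = arr[-lag_beats:]
        return out

    sbp_a = _align(np.asarray(sbp, dtype=float))
    valid = np.isfinite(rr) & (rr > 0) & np.isfinite(sbp_a)
    if pressure_valid is not None:
        valid &= _align(np.asarray(pressure_valid, dtype=float)) > 0
    return BeatSeries(t=t, rr=rr, sbp=sbp_a, dbp=_align(dbp), map=_align(map_),
                      valid=valid)


def flag_artifacts(
    series: BeatSeries,
    rel_threshold: float = ARTIFACT_REL_THRESHOLD,
    window: int = ARTIFACT_WINDOW_BEATS,
) -> BeatSeries:
    """Flag ectopic / artifactual cycles by RR deviation from a rolling median.

    A cycle is flagged when its RR interval deviates from the centered
    rolling median (window beats, shrinking at the edges) by more than
    ``rel_threshold`` x that median. Flagging is pure annotation: values are
    kept, but flagged cycles are excluded from interpolation support and
    from time-domain HRV difference pairs.
    """
    if window < 3 or window % 2 == 0:
        raise ConfigurationError("window must be odd and >= 3")
    rr = pd.Series(series.rr)
    med = rr.rolling(window, center=True, min_periods=2).median().to_numpy()
    # fall back to global median where the rolling one is undefined
    med = np.where(np.isfinite(med), med, np.nanmedian(series.rr))
    dev = np.abs(series.rr - med) > rel_threshold * med
    bad = dev | ~np.isfinite(series.rr) | (series.rr <= 0)
    return replace(series, valid=series.valid & ~bad)


def assess_suitability(
    series: BeatSeries, max_ectopic_fraction: float = MAX_ECTOPIC_FRACTION
) -> tuple[bool, str]:
    """Decide whether a session supports cBRS / HRV analysis.

    Mirrors the exclusion of recordings with frequent ectopy: suitable iff
    the flagged fraction is <= ``max_ectopic_fraction`` (boundary counts as
    suitable). Returns ``(suitable, reason)``; reason is empty when suitable.
    """
    frac = series.ectopic_fraction
    if frac <= max_ectopic_fraction:
        return True, ""
    return False, (
        f"ectopic/artifact fraction {frac:.1%} exceeds "
        f"{max_ectopic_fraction:.1%}: not suitable for cBRS and HRV analysis"
    )


def interpolate_resample(
    series: BeatSeries, channel: str = "rr", fs: float = RESAMPLE_HZ
) -> EquidistantSeries:
    """Natural cubic spline through valid cycles, resampled at ``fs``.

    The spline knots are (t_k, value_k) for valid cycles only — flagged
    beats are interpolated over. Samples are taken at
    ``t_first_valid + n / fs`` and never beyond the last valid knot.
    """
    if channel not in ("rr", "sbp", "dbp", "map"):
        raise ConfigurationError(f"unknown channel {channel!r}")
    vals = getattr(series, channel)
    m = series.valid & np.isfinite(vals)
    t = series.interval_times[m]
    v = vals[m]
    if t.size < 4:
        raise InsufficientDataError("need >= 4 valid beats for spline resampling")
    span = t[-1] - t[0]
    if span < 2.0:
        raise InsufficientDataError("valid-beat span < 2 s")
    spline = CubicSpline(t, v, bc_type="natural")
    n_out = int(np.floor(span * fs)) + 1
    tt = t[0] + np.arange(n_out) / fs
    tt = tt[tt <= t[-1] + 1e-12]
    return EquidistantSeries(fs=fs, start_s=float(t[0]), values=spline(tt),
                             source_span_s=float(span))
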