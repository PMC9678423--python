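"""Welch cross-spectral analysis and the transfer-function cBRS index.

Given the 4 Hz SBP and RR tracks, the record is split into K segments
(default 5) overlapping by 50%; each segment is linearly detrended, tapered
with a Hann window and Fourier transformed. Auto- and cross-spectra are
averaged over segments with density normalization (window power corrected,
so the integrated autospectrum matches the detrended variance).

The baroreflex transfer function from SBP (input, mmHg) to RR (output, ms)
is then

    gain(f)      = |Sxy(f)| / Sxx(f)          [ms/mmHg]
    phase(f)     = arg Sxy(f)                 [rad; negative = RR lags SBP]
    coherence(f) = |Sxy(f)|^2 / (Sxx Syy)     [0..1]

Band means over VLF (<0.04 Hz), LF (0.04-0.15 Hz) and HF (0.15-0.40 Hz) are
reported; the LF-band mean gain is the cardiac baroreflex sensitivity
(cBRS) index.

Segment length is L = floor(2N/(K+1)) (forced even), the unique choice that
covers the full record with K half-overlapping segments. Band edges are
half-open [lo, hi) with HF closed at 0.40 Hz and the DC bin excluded, so
every bin belongs to exactly one band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .beats import EquidistantSeries
from .errors import ConfigurationError, InsufficientDataError

MIN_SEGMENT_SAMPLES = 32
# input autospectrum below this density (mmHg^2/Hz) is numerical noise from
# a constant channel: the transfer function is reported missing there
SXX_FLOOR = 1e-20


@dataclass(frozen=True)
class Band:
    name: str
    lo: float
    hi: float
    hi_inclusive: bool = False

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        m = (freqs >= self.lo) & (freqs > 0)  # DC never contributes
        m &= (freqs <= self.hi) if self.hi_inclusive else (freqs < self.hi)
        return m


@dataclass(frozen=True)
class BandScheme:
    """The standard cardiovascular variability bands."""

    vlf: Band = field(default_factory=lambda: Band("vlf", 0.0, 0.04))
    lf: Band = field(default_factory=lambda: Band("lf", 0.04, 0.15))
    hf: Band = field(default_factory=lambda: Band("hf", 0.15, 0.40, hi_inclusive=True))

    def __iter__(self):
        return iter((self.vlf, self.lf, self.hf))


@dataclass
class SpectralEstimate:
    """Averaged one-sided Welch spectra of SBP (x) and RR (y)."""

    freqs: np.ndarray          # Hz
    sxx: np.ndarray            # mmHg^2/Hz
    syy: np.ndarray            # ms^2/Hz
    sxy: np.ndarray            # complex, ms*mmHg/Hz; conj(X)*Y convention
    fs: float
    n_segments: int
    segment_len_s: float
    window: str = "hann"
    detrend: str = "linear"

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandSummary:
    gain: float
    phase: float
    coherence: float
    power_x: float             # mmHg^2 (integrated sxx)
    power_y: float             # ms^2 (integrated syy)
    n_bins: int


@dataclass
class TransferFunctionResult:
    """Per-frequency transfer function plus band summaries."""

    freqs: np.ndarray
    gain: np.ndarray           # ms/mmHg; NaN where sxx == 0
    phase: np.ndarray          # rad in (-pi, pi]
    coherence: np.ndarray      # [0, 1]
    bands: dict[str, BandSummary] = field(default_factory=dict)

    @property
    def cbrs_lf_gain(self) -> float:
        """LF-band mean gain, the cBRS index (ms/mmHg)."""
        lf = self.bands.get("lf")
        return lf.gain if lf is not None else float("nan")


def segment_length(n: int, n_segments: int) -> int:
    """L = floor(2N/(K+1)), forced even so the 50% hop is integral."""
    L = (2 * n) // (n_segments + 1)
    return L - (L % 2)


def welch_cross_spectra(
    x: EquidistantSeries | np.ndarray,
    y: EquidistantSeries | np.ndarray,
    fs: float | None = None,
    n_segments: int = 5,
    overlap: float = 0.5,
    window: str = "hann",
    detrend: str = "linear",
) -> SpectralEstimate:
    """Averaged one-sided auto/cross spectra of two aligned series.

    ``x`` is the SBP track (input), ``y`` the RR track (output). Both must
    share sampling rate and length. The cross-spectrum uses the
    conj(X) * Y convention, so a delayed output yields negative phase.
    """
    if isinstance(x, EquidistantSeries):
        fs = x.fs if fs is None else fs
        if isinstance(y, EquidistantSeries) and y.fs != x.fs:
            raise ConfigurationError("x and y sampling rates differ")
        xv = x.values
    else:
        xv = np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, EquidistantSeries) else np.asarray(y, dtype=float)
    if fs is None:
        raise ConfigurationError("sampling rate required for plain arrays")
    if xv.size != yv.size:
        raise ConfigurationError(f"length mismatch: {xv.size} vs {yv.size}")
    if overlap != 0.5:
        raise ConfigurationError("only 50% overlap is supported")

    n = xv.size
    L = segment_length(n, n_segments)
    if L < MIN_SEGMENT_SAMPLES:
        raise InsufficientDataError(
            f"segment length {L} samples < {MIN_SEGMENT_SAMPLES}; record too short "
            f"for {n_segments} segments"
        )
    kw = dict(fs=fs, window=window, nperseg=L, noverlap=L // 2, detrend=detrend,
              scaling="density", return_onesided=True)
    f, sxx = sps.welch(xv, **kw)
    _, syy = sps.welch(yv, **kw)
    _, sxy = sps.csd(xv, yv, **kw)
    return SpectralEstimate(freqs=f, sxx=sxx, syy=syy, sxy=sxy, fs=fs,
                            n_segments=n_segments, segment_len_s=L / fs,
                            window=window, detrend=detrend)


def transfer_function(s: SpectralEstimate) -> TransferFunctionResult:
    """Per-frequency gain/phase/coherence from a spectral estimate.

    Frequencies where the input autospectrum vanishes yield NaN (missing)
    gain, phase and coherence rather than infinities.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.abs(s.sxy) / s.sxx
        coh = np.abs(s.sxy) ** 2 / (s.sxx * s.syy)
    phase = np.angle(s.sxy)
    undef = ~(s.sxx > max(float(np.max(s.sxx)) * 1e-12, SXX_FLOOR))
    gain[undef] = np.nan
    phase = np.where(undef, np.nan, phase)
    coh = np.where(~np.isfinite(coh), np.nan, np.clip(coh, 0.0, 1.0))
    return TransferFunctionResult(freqs=s.freqs, gain=gain, phase=phase,
                                  coherence=coh)


def band_summary(
    tf: TransferFunctionResult,
    s: SpectralEstimate | None = None,
    bands: BandScheme | None = None,
    coherence_min: float | None = None,
) -> TransferFunctionResult:
    """Attach band means (unweighted over bins) and the cBRS index.

    The statistic per band is the plain mean of per-bin gain, phase and
    coherence over bins whose center frequency falls in the band. When
    ``coherence_min`` is given, only bins at or above that coherence
    contribute; a band emptied by the gate reports NaN with n_bins = 0,
    never zero. Band powers (integrated densities, trapezoidal) are filled
    when the spectral estimate is supplied.
    """
    bands = bands or BandScheme()
    out: dict[str, BandSummary] = {}
    for band in bands:
        m = band.mask(tf.freqs)
        if not m.any():
            raise InsufficientDataError(f"no spectral bins in band {band.name}")
        m_ok = m & np.isfinite(tf.gain)
        if coherence_min is not None:
            m_ok &= tf.coherence >= coherence_min
        n_bins = int(m_ok.sum())
        if n_bins == 0:
            g = p = c = float("nan")
        else:
            g = float(np.mean(tf.gain[m_ok]))
            p = float(np.mean(tf.phase[m_ok]))
            c = float(np.mean(tf.coherence[m_ok]))
        px = py = float("nan")
        if s is not None:
            px = band_power(s.freqs, s.sxx, band)
            py = band_power(s.freqs, s.syy, band)
        out[band.name] = BandSummary(gain=g, phase=p, coherence=c,
                                     power_x=px, power_y=py, n_bins=n_bins)
    tf.bands = out
    return tf


def band_power(freqs: np.ndarray, density: np.ndarray, band: Band) -> float:
    """Integrated spectral density over a band (trapezoidal over its bins)."""
    m = band.mask(freqs)
    if m.sum() < 2:
        return float(np.sum(density[m]) * (freqs[1] - freqs[0]))
    return float(np.trapezoid(density[m], freqs[m]))
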