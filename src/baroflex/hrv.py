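"""Heart-rate variability metrics (Task-Force style).

Time domain (computed on the raw, unevenly sampled beat series):

    RMSSD  = sqrt( mean_k (rr_{k+1} - rr_k)^2 )            [ms]
    pNN50  = 100 * #{k : |rr_{k+1} - rr_k| > 50 ms} / pairs [%]

Successive-difference pairs that span a flagged (ectopic/artifact) cycle
are excluded; the ">50 ms" comparison is strict.

Frequency domain (computed on the 4 Hz resampled RR track through the same
Welch machinery as the transfer-function analysis): band powers are the
integrated RR autospectrum over VLF/LF/HF; total power = VLF+LF+HF and

    LFnu = 100 * LF / (total - VLF),   HFnu = 100 * HF / (total - VLF)

so LFnu + HFnu = 100 identically. LF/HF is the ratio of absolute powers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import EquidistantSeries
from .errors import InsufficientDataError
from .spectral import BandScheme, SpectralEstimate, band_power, welch_cross_spectra

NN_THRESHOLD_MS = 50.0
# band powers below this (ms^2) are numerical residue of a constant series;
# ratios built on them are reported missing
POWER_FLOOR_MS2 = 1e-12


@dataclass
class HRVSummary:
    mean_rr: float = float("nan")    # ms
    hr: float = float("nan")         # beats/min = 60000 / mean_rr
    rmssd: float = float("nan")      # ms
    pnn50: float = float("nan")      # %
    vlf_power: float = float("nan")  # ms^2
    lf_power: float = float("nan")   # ms^2
    hf_power: float = float("nan")   # ms^2
    lf_nu: float = float("nan")      # %
    hf_nu: float = float("nan")      # %
    lf_hf: float = float("nan")      # ratio (AU)
    total_power: float = float("nan")  # ms^2 (VLF+LF+HF by default)


def time_domain(
    rr: np.ndarray, valid: np.ndarray | None = None, exclude_flagged_pairs: bool = True
) -> HRVSummary:
    """Mean RR, HR, RMSSD and pNN50 from a beat-by-beat RR series (ms)."""
    rr = np.asarray(rr, dtype=float)
    if valid is None:
        valid = np.isfinite(rr) & (rr > 0)
    valid = np.asarray(valid, dtype=bool)
    good = rr[valid]
    if good.size < 3:
        raise InsufficientDataError("need >= 3 valid RR intervals for time-domain HRV")
    if exclude_flagged_pairs:
        pair_ok = valid[:-1] & valid[1:]
        diffs = rr[1:][pair_ok] - rr[:-1][pair_ok]
    else:
        diffs = np.diff(rr)
    if diffs.size == 0:
        raise InsufficientDataError("no consecutive valid RR pairs")
    mean_rr = float(np.mean(good))
    return HRVSummary(
        mean_rr=mean_rr,
        hr=60000.0 / mean_rr,
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        pnn50=100.0 * float(np.count_nonzero(np.abs(diffs) > NN_THRESHOLD_MS))
        / diffs.size,
    )


def frequency_domain(
    rr_eq: EquidistantSeries | None = None,
    bands: BandScheme | None = None,
    spectrum: SpectralEstimate | None = None,
    n_segments: int = 5,
    total_to_nyquist: bool = False,
) -> HRVSummary:
    """Band powers, normalized units and LF/HF from the resampled RR track.

    Either pass ``rr_eq`` (the RR autospectrum is then estimated with the
    same Welch settings as the transfer-function stage) or an existing
    ``spectrum`` whose ``syy`` is the RR autospectrum — the latter guarantees
    bit-identical powers between the HRV and cBRS reports.
    """
    if spectrum is None:
        if rr_eq is None:
            raise ValueError("pass rr_eq or spectrum")
        spectrum = welch_cross_spectra(rr_eq, rr_eq, n_segments=n_segments)
    bands = bands or BandScheme()
    vlf = band_power(spectrum.freqs, spectrum.syy, bands.vlf)
    lf = band_power(spectrum.freqs, spectrum.syy, bands.lf)
    hf = band_power(spectrum.freqs, spectrum.syy, bands.hf)
    if total_to_nyquist:
        total = float(np.trapezoid(spectrum.syy[spectrum.freqs > 0],
                                   spectrum.freqs[spectrum.freqs > 0]))
    else:
        total = vlf + lf + hf
    denom = total - vlf
    lf_nu = 100.0 * lf / denom if denom > POWER_FLOOR_MS2 else float("nan")
    hf_nu = 100.0 * hf / denom if denom > POWER_FLOOR_MS2 else float("nan")
    lf_hf = lf / hf if hf > POWER_FLOOR_MS2 else float("nan")
    return HRVSummary(vlf_power=vlf, lf_power=lf, hf_power=hf,
                      lf_nu=lf_nu, hf_nu=hf_nu, lf_hf=lf_hf, total_power=total)


def combine(td: HRVSummary, fd: HRVSummary) -> HRVSummary:
    """Merge time-domain and frequency-domain halves into one summary."""
    return HRVSummary(
        mean_rr=td.mean_rr, hr=td.hr, rmssd=td.rmssd, pnn50=td.pnn50,
        vlf_power=fd.vlf_power, lf_power=fd.lf_power, hf_power=fd.hf_power,
        lf_nu=fd.lf_nu, hf_nu=fd.hf_nu, lf_hf=fd.lf_hf,
        total_power=fd.total_power,
    )
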