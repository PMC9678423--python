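"""Session-level orchestration: waveforms -> beats -> spectra -> cBRS/HRV.

``analyze_session`` runs the full chain on either a raw
:class:`~baroflex.io.WaveformRecord` or a pre-extracted
:class:`~baroflex.beats.BeatSeries` and returns one :class:`SessionResult`
that mirrors a single row of a physiological summary table: ventilation,
hemodynamics, transfer-function cBRS, and HRV, plus provenance (every
stage parameter actually used). The function is pure: identical input and
configuration produce identical JSON.

Also here: the inspired-O2 fraction utility for hypobaric chambers
(Fo2 = PIO2_target / (P_B - 47 mmHg), water vapor pressure at 37 C), and
descriptive group summaries (mean +/- SD or median [IQR] per a supplied
normality flag; inferential statistics are deliberately out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import hrv as hrv_mod
from .beats import (
    ARTIFACT_REL_THRESHOLD,
    ARTIFACT_WINDOW_BEATS,
    MAX_ECTOPIC_FRACTION,
    RESAMPLE_HZ,
    BeatSeries,
    assess_suitability,
    build_beat_series,
    flag_artifacts,
    interpolate_resample,
)
from .detect import (
    VentilationSummary,
    detect_breaths,
    detect_r_peaks,
    extract_pressure_beats,
)
from .errors import (
    ConfigurationError,
    DataError,
    InsufficientDataError,
    SignalQualityError,
    SuitabilityError,
)
from .io import WaveformRecord
from .spectral import (
    BandScheme,
    SpectralEstimate,
    TransferFunctionResult,
    band_summary,
    transfer_function,
    welch_cross_spectra,
)

logger = logging.getLogger("baroflex")

WATER_VAPOR_37C_MMHG = 47.0
SEA_LEVEL_PIO2_TARGET_MMHG = 145.0


@dataclass
class AnalysisConfig:
    """Every tunable of the analysis chain, recorded into each result."""

    resample_hz: float = RESAMPLE_HZ
    n_segments: int = 5
    overlap: float = 0.5
    window: str = "hann"
    detrend: str = "linear"
    bands: BandScheme = field(default_factory=BandScheme)
    coherence_min: float | None = None
    lag_beats: int = 0
    artifact_rel_threshold: float = ARTIFACT_REL_THRESHOLD
    artifact_window_beats: int = ARTIFACT_WINDOW_BEATS
    max_ectopic_fraction: float = MAX_ECTOPIC_FRACTION
    force: bool = False


@dataclass
class SessionResult:
    """All quantities reported for one recording session."""

    meta: dict = field(default_factory=dict)
    ventilation: VentilationSummary | None = None
    sbp_mmhg: float = float("nan")
    dbp_mmhg: float = float("nan")
    map_mmhg: float = float("nan")
    hr_beats_per_min: float = float("nan")
    rr_s: float = float("nan")
    tf: TransferFunctionResult | None = None
    hrv: hrv_mod.HRVSummary | None = None
    suitable: bool = True
    suitability_reason: str = ""
    ectopic_fraction: float = 0.0
    params: dict = field(default_factory=dict)

    def to_flat_dict(self) -> dict[str, Any]:
        """One flat row with unit-suffixed keys (CSV / JSON schema)."""
        nan = float("nan")
        lf = self.tf.bands.get("lf") if self.tf is not None else None
        h = self.hrv
        return {
            "participant": self.meta.get("participant"),
            "day": self.meta.get("day"),
            "trial": self.meta.get("trial"),
            "spo2_pct": self.meta.get("spo2_pct"),
            "ve_l_per_min": self.ventilation.ve if self.ventilation else None,
            "rf_breaths_per_min": self.ventilation.rf if self.ventilation else None,
            "vt_l": self.ventilation.vt_mean if self.ventilation else None,
            "sbp_mmhg": self.sbp_mmhg,
            "dbp_mmhg": self.dbp_mmhg,
            "map_mmhg": self.map_mmhg,
            "hr_beats_per_min": self.hr_beats_per_min,
            "rr_s": self.rr_s,
            "cbrs_lf_gain_ms_per_mmhg": lf.gain if lf else nan,
            "cbrs_lf_phase_rad": lf.phase if lf else nan,
            "cbrs_lf_coherence": lf.coherence if lf else nan,
            "vlf_power_ms2": h.vlf_power if h else nan,
            "lf_power_ms2": h.lf_power if h else nan,
            "hf_power_ms2": h.hf_power if h else nan,
            "lf_power_pct": h.lf_nu if h else nan,
            "hf_power_pct": h.hf_nu if h else nan,
            "lf_hf_au": h.lf_hf if h else nan,
            "pnn50_pct": h.pnn50 if h else nan,
            "rmssd_ms": h.rmssd if h else nan,
            "suitable": self.suitable,
            "ectopic_fraction": self.ectopic_fraction,
        }

    def to_json_dict(self) -> dict[str, Any]:
        out = {k: _jsonable(v) for k, v in self.to_flat_dict().items()}
        out["suitability_reason"] = self.suitability_reason
        if self.tf is not None:
            out["bands"] = {
                name: {
                    "gain_ms_per_mmhg": _jsonable(b.gain),
                    "phase_rad": _jsonable(b.phase),
                    "coherence": _jsonable(b.coherence),
                    "sbp_power_mmhg2": _jsonable(b.power_x),
                    "rr_power_ms2": _jsonable(b.power_y),
                    "n_bins": b.n_bins,
                }
                for name, b in self.tf.bands.items()
            }
        out["params"] = {k: _jsonable(v) for k, v in self.params.items()}
        return out


def _jsonable(v):
    if isinstance(v, (np.floating, float)):
        v = float(v)
        return None if np.isnan(v) else v
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.bool_, bool)):
        return bool(v)
    return v


def analyze_session(
    source: WaveformRecord | BeatSeries,
    cfg: AnalysisConfig | None = None,
    meta: dict | None = None,
) -> SessionResult:
    """Run the full analysis chain on one recording.

    Raw waveforms go through beat/breath detection first; a pre-extracted
    beat series skips straight to artifact flagging. Sessions whose flagged
    ectopic fraction exceeds ``cfg.max_ectopic_fraction`` raise
    :class:`SuitabilityError` unless ``cfg.force`` is set, in which case all
    quantities are still computed but the result is marked unsuitable.
    """
    cfg = cfg or AnalysisConfig()
    meta = dict(meta or {})
    ventilation: VentilationSummary | None = None

    if isinstance(source, WaveformRecord):
        meta = {**source.meta, **meta}
        if "ecg" not in source.channels or "bp" not in source.channels:
            raise ConfigurationError("waveform input needs 'ecg' and 'bp' channels")
        ann = detect_r_peaks(source.channels["ecg"], source.fs)
        sbp, dbp, map_, pvalid = extract_pressure_beats(
            source.channels["bp"], source.fs, ann
        )
        series = build_beat_series(ann, sbp, dbp, map_, pressure_valid=pvalid,
                                   lag_beats=cfg.lag_beats)
        if "flow" in source.channels:
            try:
                ventilation = detect_breaths(source.channels["flow"], source.fs)
            except (SignalQualityError, InsufficientDataError) as exc:
                logger.warning("ventilation unavailable: %s", exc)
    else:
        series = source

    series = flag_artifacts(series, cfg.artifact_rel_threshold,
                            cfg.artifact_window_beats)
    suitable, reason = assess_suitability(series, cfg.max_ectopic_fraction)
    if not suitable and not cfg.force:
        raise SuitabilityError(reason, ectopic_fraction=series.ectopic_fraction)

    res = SessionResult(meta=meta, ventilation=ventilation, suitable=suitable,
                        suitability_reason=reason,
                        ectopic_fraction=series.ectopic_fraction)

    v = series.valid
    for attr, vals in (("sbp_mmhg", series.sbp), ("dbp_mmhg", series.dbp),
                       ("map_mmhg", series.map)):
        good = vals[v]
        good = good[np.isfinite(good)]
        setattr(res, attr, float(np.mean(good)) if good.size else float("nan"))

    td = hrv_mod.time_domain(series.rr, series.valid)
    res.rr_s = td.mean_rr / 1000.0
    res.hr_beats_per_min = td.hr

    rr_eq = interpolate_resample(series, "rr", cfg.resample_hz)
    sbp_eq = interpolate_resample(series, "sbp", cfg.resample_hz)
    est = welch_cross_spectra(sbp_eq, rr_eq, n_segments=cfg.n_segments,
                              overlap=cfg.overlap, window=cfg.window,
                              detrend=cfg.detrend)
    tf = band_summary(transfer_function(est), s=est, bands=cfg.bands,
                      coherence_min=cfg.coherence_min)
    fd = hrv_mod.frequency_domain(spectrum=est, bands=cfg.bands)
    res.tf = tf
    res.hrv = hrv_mod.combine(td, fd)

    res.params = {
        "resample_hz": cfg.resample_hz,
        "n_segments": cfg.n_segments,
        "overlap": cfg.overlap,
        "window": cfg.window,
        "detrend": cfg.detrend,
        "segment_len_s": est.segment_len_s,
        "freq_resolution_hz": est.df,
        "bins_per_band": {name: b.n_bins for name, b in tf.bands.items()},
        "coherence_min": cfg.coherence_min,
        "lag_beats": cfg.lag_beats,
        "artifact_rel_threshold": cfg.artifact_rel_threshold,
        "artifact_window_beats": cfg.artifact_window_beats,
        "max_ectopic_fraction": cfg.max_ectopic_fraction,
        "n_beats": len(series),
    }
    logger.info(
        "session analyzed: %d beats, segment %.1f s, df=%.4f Hz, bins/band %s",
        len(series), est.segment_len_s, est.df, res.params["bins_per_band"],
    )
    return res


def required_o2_fraction(
    pb_mmhg: float,
    pio2_target_mmhg: float = SEA_LEVEL_PIO2_TARGET_MMHG,
    ph2o_mmhg: float = WATER_VAPOR_37C_MMHG,
) -> float:
    """O2 fraction needed to reach a target inspired PO2 at pressure ``pb``.

    Fo2 = PIO2_target / (P_B - P_H2O), with P_H2O the 37 C saturated water
    vapor pressure (47 mmHg). E.g. restoring a 145 mmHg PIO2 at a chamber
    pressure of 493.5 mmHg requires a fraction of 0.3247 (32%).
    """
    if pb_mmhg <= ph2o_mmhg:
        raise ConfigurationError(
            f"barometric pressure {pb_mmhg} mmHg must exceed water vapor "
            f"pressure {ph2o_mmhg} mmHg"
        )
    if pio2_target_mmhg >= pb_mmhg - ph2o_mmhg:
        raise ConfigurationError("target PIO2 unreachable below 100% O2")
    return pio2_target_mmhg / (pb_mmhg - ph2o_mmhg)


def format_o2_percent(fraction: float) -> str:
    """Round an O2 fraction to the nearest integer percent, e.g. '32%'."""
    return f"{round(100 * fraction)}%"


def group_summary(
    sessions: pd.DataFrame,
    variables: list[str],
    normal_flags: dict[str, bool] | None = None,
    group_by: list[str] | None = None,
    min_n: int = 2,
) -> pd.DataFrame:
    """Descriptive statistics per condition and variable.

    Normally distributed variables (``normal_flags[var] is True``, the
    default) are summarized as mean +/- sample SD (ddof=1); the rest as
    median [IQR] with quartiles by linear interpolation between order
    statistics. ``n`` counts non-missing sessions per variable. Inferential
    tests are not computed here.
    """
    normal_flags = normal_flags or {}
    if group_by:
        grouped = list(sessions.groupby(group_by, dropna=False))
    else:
        grouped = [(("all",), sessions)]
    rows = []
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        label = "/".join(str(k) for k in key)
        if len(sub) < min_n:
            raise DataError(
                f"condition {label!r} has {len(sub)} session(s); need >= {min_n}"
            )
        for var in variables:
            vals = pd.to_numeric(sub[var], errors="coerce").dropna().to_numpy()
            row: dict[str, Any] = {"condition": label, "variable": var,
                                   "n": int(vals.size)}
            if vals.size == 0:
                rows.append(row)
                continue
            if normal_flags.get(var, True):
                m = float(np.mean(vals))
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
                row.update(mean=m, sd=sd, summary=f"{m:g} ± {sd:g}")
            else:
                med = float(np.median(vals))
                q1, q3 = (float(q) for q in
                          np.percentile(vals, [25, 75], method="linear"))
                row.update(median=med, q1=q1, q3=q3,
                           summary=f"{med:g} [{q1:g}–{q3:g}]")
            rows.append(row)
    return pd.DataFrame(rows)
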