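"""On-disk formats: delimited waveform exports, beat tables, result files.

Waveforms travel as tab- or comma-delimited text with one header row, one
column per channel, and an externally supplied sampling rate (chart-recorder
exports carry no self-describing metadata). Beat tables are CSV with the
fixed dialect below. All write/read round-trips are lossless to 1e-9
relative (waveforms bit-exactly), and readers never silently drop rows:
every exclusion is either flagged or raised.

Beat-table dialect (comma, point decimal, header required)::

    t_s, rr_ms, sbp_mmhg, dbp_mmhg, map_mmhg, valid

One row per beat; the cycle fields (rr/sbp/dbp/map/valid) of row k describe
the cardiac cycle opened by beat k, so the last row leaves them empty.
Empty fields are read back as NaN with the cycle flagged invalid.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import BeatSeries
from .errors import ConfigurationError, DataError, FormatError

BEAT_TABLE_COLUMNS = ["t_s", "rr_ms", "sbp_mmhg", "dbp_mmhg", "map_mmhg", "valid"]

#: One row per analyzed session, in the conventional report order
#: (oximetry, ventilation, hemodynamics, cBRS, HRV spectral, HRV time-domain).
SESSION_CSV_COLUMNS = [
    "participant", "day", "trial",
    "spo2_pct",
    "ve_l_per_min", "rf_breaths_per_min", "vt_l",
    "sbp_mmhg", "dbp_mmhg", "map_mmhg", "hr_beats_per_min", "rr_s",
    "cbrs_lf_gain_ms_per_mmhg", "cbrs_lf_phase_rad", "cbrs_lf_coherence",
    "vlf_power_ms2", "lf_power_ms2", "hf_power_ms2",
    "lf_power_pct", "hf_power_pct", "lf_hf_au",
    "pnn50_pct", "rmssd_ms",
    "suitable", "ectopic_fraction",
]


@dataclass
class WaveformRecord:
    """Uniformly sampled multi-channel raw signals.

    channels maps channel name -> sample array (conventional units:
    ecg mV, bp mmHg, flow L/s); fs is the sampling rate in Hz; t0 the
    recording start offset in seconds.
    """

    channels: dict[str, np.ndarray]
    fs: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channels:
            raise ValueError("at least one channel required")
        lengths = set()
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            self.channels[name] = arr
            lengths.add(arr.size)
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        if lengths.pop() < 2:
            raise ValueError("channels must hold at least 2 samples")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


def _sniff_delimiter(path: Path) -> str:
    head = path.open("r").readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_waveform_delimited(
    path: str | Path,
    fs: float,
    column_map: dict[str, str] | None = None,
    time_column: str | None = None,
    t0: float = 0.0,
    meta: dict | None = None,
) -> WaveformRecord:
    """Read a delimited waveform export.

    ``column_map`` maps file column -> channel name (e.g. ``{"CH1": "ecg"}``);
    when omitted every column is taken as a channel under its own name.
    ``time_column`` optionally names a time column used only for a
    monotonicity check — the sample clock is always ``fs``.
    """
    path = Path(path)
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    df = pd.read_csv(path, sep=_sniff_delimiter(path), skip_blank_lines=False,
                     float_precision="round_trip")
    if time_column is not None:
        if time_column not in df.columns:
            raise FormatError(f"time column {time_column!r} missing from {path}")
        tcol = df[time_column].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(tcol) <= 0)
        if bad.size:
            raise FormatError(
                f"non-monotonic time at row {int(bad[0]) + 1} in {path}"
            )
    if column_map is None:
        column_map = {c: c for c in df.columns if c != time_column}
    channels: dict[str, np.ndarray] = {}
    for col, chan in column_map.items():
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
        arr = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise DataError(
                f"non-finite sample in column {col!r} at row {int(bad[0])}"
            )
        channels[chan] = arr
    return WaveformRecord(channels=channels, fs=fs, t0=t0, meta=dict(meta or {}))


def write_waveform(record: WaveformRecord, path: str | Path, delimiter: str = "\t") -> None:
    """Write a waveform record; floats at full precision (bit-exact reread)."""
    df = pd.DataFrame({k: v for k, v in record.channels.items()})
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_beat_table(path: str | Path) -> BeatSeries:
    """Read a beat-table CSV (dialect in the module docstring).

    Rows violating the physiological invariants (rr <= 0, sbp <= dbp,
    missing values) are flagged invalid, never dropped. A non-increasing
    beat time aborts with the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in BEAT_TABLE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise FormatError(f"beat table {path} missing columns: {missing}")
    t = df["t_s"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise FormatError(f"beat table {path}: non-finite t_s")
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise FormatError(
            f"beat table {path}: t_s not strictly increasing at row {int(bad[0]) + 1}"
        )
    n = t.size
    if n < 2:
        raise FormatError(f"beat table {path}: need at least 2 beats")

    def cycle_col(name: str) -> np.ndarray:
        return df[name].to_numpy(dtype=float)[: n - 1]

    rr = cycle_col("rr_ms")
    sbp = cycle_col("sbp_mmhg")
    dbp = cycle_col("dbp_mmhg")
    map_ = cycle_col("map_mmhg")
    if "valid" in df.columns:
        vcol = df["valid"].to_numpy(dtype=float)[: n - 1]
        valid = np.where(np.isfinite(vcol), vcol, 1.0) > 0
    else:
        valid = np.ones(n - 1, dtype=bool)
    valid &= np.isfinite(rr) & (rr > 0) & np.isfinite(sbp)
    with np.errstate(invalid="ignore"):
        valid &= ~(np.isfinite(dbp) & (sbp <= dbp))
    return BeatSeries(t=t, rr=rr, sbp=sbp, dbp=dbp, map=map_, valid=valid)


def write_beat_table(series: BeatSeries, path: str | Path) -> None:
    """Write a beat series in the beat-table dialect (NaN -> empty field)."""
    n = len(series)
    pad = lambda a: np.r_[a, np.nan]  # noqa: E731  - last beat has no cycle
    df = pd.DataFrame(
        {
            "t_s": series.t,
            "rr_ms": pad(series.rr),
            "sbp_mmhg": pad(series.sbp),
            "dbp_mmhg": pad(series.dbp),
            "map_mmhg": pad(series.map),
            "valid": pad(series.valid.astype(float)),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_results(result, path: str | Path, format: str = "json") -> None:
    """Write a SessionResult as JSON (stable documented keys) or one-row CSV.

    The CSV columns are exactly :data:`SESSION_CSV_COLUMNS`; the JSON carries
    the same flat keys plus the provenance parameter block.
    """
    path = Path(path)
    if format == "json":
        payload = result.to_json_dict()
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif format == "csv":
        row = result.to_flat_dict()
        with path.open("w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=SESSION_CSV_COLUMNS,
                               extrasaction="ignore")
            w.writeheader()
            w.writerow({k: _fmt(row.get(k)) for k in SESSION_CSV_COLUMNS})
    else:
        raise ConfigurationError(f"unsupported results format {format!r} (csv|json)")


def write_spectra(tf, estimate, path: str | Path) -> None:
    """Per-frequency diagnostic export."""
    pd.DataFrame(
        {
            "freq_hz": estimate.freqs,
            "sxx_mmhg2_per_hz": estimate.sxx,
            "syy_ms2_per_hz": estimate.syy,
            "gain_ms_per_mmhg": tf.gain,
            "phase_rad": tf.phase,
            "coherence": tf.coherence,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def _fmt(v):
    if v is None:
        return ""
    if isinstance(v, float) and math.isnan(v):
        return ""
    return v
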