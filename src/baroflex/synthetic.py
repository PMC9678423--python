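"""Closed-loop cardiovascular variability simulator.

Generates beat-by-beat SBP and RR series with a known, programmable
baroreflex coupling so that every pipeline stage can be validated by
parameter recovery. The model is event-driven: systolic pressure at each
beat carries a Mayer-wave (~0.1 Hz) and a respiratory (~0.25 Hz)
oscillation plus noise; the RR interval responds to SBP ``delay_beats``
beats earlier with gain ``gain_true`` (ms/mmHg), plus direct respiratory
sinus arrhythmia and noise; the next beat occurs one RR interval later:

    sbp_k = sbp0 + a_lf sin(2 pi f_lf t_k) + a_hf sin(2 pi f_hf t_k) + eps_k
    rr_k  = rr0 + G (sbp_{k-d} - sbp0) + rsa_ms sin(2 pi f_hf t_k) + eta_k
    t_{k+1} = t_k + rr_k / 1000

At the Mayer-wave frequency the SBP->RR transfer function of this system
is analytically the programmed gain G with delay phase, which is what the
recovery tests exploit. Ectopy is emulated by halving RR at random beats.

Condition presets encode the direction and magnitude of the group-level
changes observed across a normobaric baseline day and two hypobaric-hypoxia
days (heart rate up; RR interval, cBRS gain and HF power down; respiratory
rate up), plus hyperoxic restoration and controlled-breathing variants.
Preset constants are documented package choices, not fitted values.

Raw-waveform synthesis turns a beat series back into ECG / arterial
pressure / respiratory flow traces so the waveform-level detectors can be
validated round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .beats import BeatSeries
from .detect import BeatAnnotations  # noqa: F401  (re-exported for callers)
from .errors import ConfigurationError
from .io import WaveformRecord

DEFAULT_PULSE_PRESSURE_MMHG = 45.0
LEAD_IN_S = 1.0                # first beat offset so waveforms render a full QRS
ECG_R_WIDTH_S = 0.020          # full width of the synthetic Gaussian R wave
SYSTOLIC_PEAK_PHASE = 0.30     # fraction of the cycle at which SBP peaks


@dataclass
class SimulationConfig:
    """Parameters of one simulated 5-min resting recording."""

    duration_s: float = 300.0      # 5 min of spontaneous breathing
    rr0: float = 800.0             # ms, baseline RR interval
    sbp0: float = 120.0            # mmHg, baseline systolic pressure
    gain_true: float = 10.0        # ms/mmHg, programmed baroreflex gain
    delay_beats: int = 1           # baroreflex latency in beats
    a_lf: float = 3.0              # mmHg, Mayer-wave SBP amplitude
    f_lf: float = 0.10             # Hz, Mayer-wave frequency
    a_hf: float = 2.0              # mmHg, respiratory SBP amplitude
    f_hf: float = 0.25             # Hz, respiratory frequency
    rsa_ms: float = 20.0           # ms, direct respiratory RR modulation
    sbp_noise_sd: float = 1.0      # mmHg
    rr_noise_sd: float = 5.0       # ms
    ectopic_rate: float = 0.0      # per-beat probability of a half-RR ectopic
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.04 <= self.f_lf < 0.15):
            raise ConfigurationError("f_lf must lie in the LF band [0.04, 0.15)")
        if not (0.15 <= self.f_hf <= 0.40):
            raise ConfigurationError("f_hf must lie in the HF band [0.15, 0.40]")
        if not (300.0 <= self.rr0 <= 2000.0):
            raise ConfigurationError("rr0 must be in [300, 2000] ms")
        for name in ("a_lf", "a_hf", "rsa_ms", "sbp_noise_sd", "rr_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.delay_beats < 0:
            raise ConfigurationError("delay_beats must be >= 0")
        if not (0.0 <= self.ectopic_rate < 1.0):
            raise ConfigurationError("ectopic_rate must be in [0, 1)")
        # worst-case deterministic drive plus a 5-sigma noise margin, halved
        # once for a potential ectopic, must keep RR positive
        worst = (
            self.rr0
            - abs(self.gain_true) * (self.a_lf + self.a_hf + 5 * self.sbp_noise_sd)
            - self.rsa_ms
            - 5 * self.rr_noise_sd
        )
        if worst * 0.5 <= 0:
            raise ConfigurationError(
                "parameters can drive RR <= 0; reduce gain/amplitudes/noise"
            )


@dataclass
class GroundTruth:
    """Bookkeeping emitted alongside every simulated series."""

    t: np.ndarray                  # beat times, s (n)
    rr_clean: np.ndarray           # ms, pre-noise pre-ectopy (n-1)
    sbp_clean: np.ndarray          # mmHg, pre-noise (n-1)
    ectopic_indices: np.ndarray    # cycle indices where RR was halved
    gain_true: float               # ms/mmHg
    expected_band_powers: dict[str, float] = field(default_factory=dict)


def simulate_beat_series(cfg: SimulationConfig) -> tuple[BeatSeries, GroundTruth]:
    """Run the closed-loop model; fully reproducible from ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_sbp, rng_rr, rng_ect = (np.random.default_rng(s) for s in ss.spawn(3))

    t_list = [LEAD_IN_S]
    sbp_list: list[float] = []
    sbp_clean: list[float] = []
    rr_list: list[float] = []
    rr_clean: list[float] = []
    ect_idx: list[int] = []
    k = 0
    while t_list[-1] < cfg.duration_s + LEAD_IN_S:
        t_k = t_list[-1]
        drive = cfg.a_lf * np.sin(2 * np.pi * cfg.f_lf * t_k) + cfg.a_hf * np.sin(
            2 * np.pi * cfg.f_hf * t_k
        )
        sbp_c = cfg.sbp0 + drive
        sbp_k = sbp_c + rng_sbp.normal(0.0, cfg.sbp_noise_sd)
        sbp_clean.append(sbp_c)
        sbp_list.append(sbp_k)

        j = k - cfg.delay_beats
        sbp_delayed = sbp_list[j] if j >= 0 else cfg.sbp0
        rr_c = (
            cfg.rr0
            + cfg.gain_true * (sbp_delayed - cfg.sbp0)
            + cfg.rsa_ms * np.sin(2 * np.pi * cfg.f_hf * t_k)
        )
        rr_k = rr_c + rng_rr.normal(0.0, cfg.rr_noise_sd)
        rr_clean.append(rr_c)
        if cfg.ectopic_rate > 0 and rng_ect.random() < cfg.ectopic_rate:
            rr_k *= 0.5
            ect_idx.append(k)
        if rr_k <= 0:
            raise ConfigurationError("simulation produced a non-positive RR interval")
        rr_list.append(rr_k)
        t_list.append(t_k + rr_k / 1000.0)
        k += 1

    t = np.asarray(t_list)
    sbp = np.asarray(sbp_list)
    rr = np.asarray(rr_list)
    dbp = sbp - DEFAULT_PULSE_PRESSURE_MMHG
    series = BeatSeries(
        t=t, rr=rr, sbp=sbp, dbp=dbp, map=dbp + (sbp - dbp) / 3.0,
        valid=np.ones(rr.size, dtype=bool),
    )
    # analytic per-band RR power expectations (LF from the baroreflex drive,
    # HF from the in-phase sum of reflex and direct respiratory modulation)
    g = abs(cfg.gain_true)
    truth = GroundTruth(
        t=t,
        rr_clean=np.asarray(rr_clean),
        sbp_clean=np.asarray(sbp_clean),
        ectopic_indices=np.asarray(ect_idx, dtype=int),
        gain_true=cfg.gain_true,
        expected_band_powers={
            "lf_rr_ms2": (g * cfg.a_lf) ** 2 / 2.0,
            "hf_rr_ms2": (g * cfg.a_hf + cfg.rsa_ms) ** 2 / 2.0,
            "lf_sbp_mmhg2": cfg.a_lf**2 / 2.0,
            "hf_sbp_mmhg2": cfg.a_hf**2 / 2.0,
        },
    )
    return series, truth


def synthesize_waveforms(
    bs: BeatSeries,
    fs: float = 500.0,
    ecg_snr_db: float | None = None,
    resp_freq_hz: float = 0.25,
    vt_l: float = 0.85,
    seed: int = 0,
    meta: dict | None = None,
) -> WaveformRecord:
    """Render a beat series as raw ECG / arterial pressure / flow waveforms.

    ECG is a train of unit-amplitude Gaussian R waves (20 ms width) at the
    beat times, optionally degraded with white noise at the requested
    mean-power signal-to-noise ratio. Arterial pressure follows a smooth
    per-cycle template rising from DBP to SBP at 30% of the cycle and
    relaxing back to DBP; where the series carries no DBP, SBP minus a
    45 mmHg pulse pressure is used. Flow is a sinusoid at ``resp_freq_hz``
    whose amplitude yields tidal volume ``vt_l`` per breath.
    """
    if fs < 100:
        raise ConfigurationError("waveform synthesis needs fs >= 100 Hz")
    t_end = bs.t[-1] + 1.0
    n = int(np.ceil(t_end * fs))
    tt = np.arange(n) / fs

    # --- ECG ---------------------------------------------------------------
    ecg = np.zeros(n)
    sigma = ECG_R_WIDTH_S / 2.355  # width taken as FWHM
    half = int(5 * sigma * fs) + 1
    for tk in bs.t:
        c = int(round(tk * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        ecg[lo:hi] += np.exp(-((tt[lo:hi] - tk) ** 2) / (2 * sigma**2))
    if ecg_snr_db is not None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        p_sig = float(np.mean(ecg**2))
        ecg = ecg + rng.normal(0.0, np.sqrt(p_sig / 10 ** (ecg_snr_db / 10)), n)

    # --- arterial pressure -------------------------------------------------
    sbp = bs.sbp
    dbp = np.where(np.isfinite(bs.dbp), bs.dbp, sbp - DEFAULT_PULSE_PRESSURE_MMHG)
    bp = np.full(n, float(dbp[-1]) if dbp.size else 80.0)
    for k in range(bs.rr.size):
        i0 = int(round(bs.t[k] * fs))
        i1 = int(round(bs.t[k + 1] * fs))
        if i1 <= i0:
            continue
        phase = (np.arange(i0, min(i1, n)) / fs - bs.t[k]) / (bs.t[k + 1] - bs.t[k])
        shape = np.where(
            phase < SYSTOLIC_PEAK_PHASE,
            np.sin(np.pi * phase / (2 * SYSTOLIC_PEAK_PHASE)) ** 2,
            np.cos(np.pi * (phase - SYSTOLIC_PEAK_PHASE)
                   / (2 * (1 - SYSTOLIC_PEAK_PHASE))) ** 2,
        )
        bp[i0 : min(i1, n)] = dbp[k] + (sbp[k] - dbp[k]) * shape
    bp[: int(round(bs.t[0] * fs))] = dbp[0] if dbp.size else 80.0
    tail = int(round(bs.t[-1] * fs))
    bp[tail:] = dbp[-1] if dbp.size else 80.0

    # --- respiratory flow --------------------------------------------------
    amp = vt_l * np.pi * resp_freq_hz  # integral of the positive half-sine = VT
    flow = amp * np.sin(2 * np.pi * resp_freq_hz * tt)

    return WaveformRecord(
        channels={"ecg": ecg, "bp": bp, "flow": flow}, fs=fs, t0=0.0,
        meta=dict(meta or {}),
    )


# Preset constants: baseline levels follow the reported group means (HR /
# RR interval / SBP and the cBRS gains 12.5, 8.9, 7.4 and 10.6 ms/mmHg);
# oscillation amplitudes are chosen so LF and HF RR powers land near the
# reported medians; respiratory frequency tracks the reported Rf drift.
_PRESETS: dict[str, dict] = {
    "day0": dict(rr0=870.0, sbp0=126.0, gain_true=12.5, a_lf=2.5, f_hf=0.23,
                 rsa_ms=35.0),
    "day1": dict(rr0=700.0, sbp0=123.0, gain_true=8.9, a_lf=2.8, f_hf=0.27,
                 rsa_ms=18.0),
    "day4": dict(rr0=750.0, sbp0=125.0, gain_true=7.4, a_lf=3.0, f_hf=0.30,
                 rsa_ms=15.0),
    "hyperoxia": dict(rr0=760.0, sbp0=122.0, gain_true=10.6, a_lf=2.8, f_hf=0.27,
                      rsa_ms=18.0),
    "controlled": dict(rr0=710.0, sbp0=131.0, gain_true=8.9, a_lf=2.8, f_hf=0.25,
                       rsa_ms=18.0),
}
_PRESET_COMMON = dict(duration_s=300.0, delay_beats=1, f_lf=0.10, a_hf=2.0,
                      sbp_noise_sd=1.5, rr_noise_sd=4.0, ectopic_rate=0.0)


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named condition presets (day0 | day1 | day4 | hyperoxia | controlled)."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(_PRESETS))}"
        )
    params = {**_PRESET_COMMON, **_PRESETS[name], "seed": seed, **overrides}
    return SimulationConfig(**params)
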