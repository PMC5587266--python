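"""Call segmentation, pulse detection, call typing, and short-call features.

The advertisement calls of *Buergeria* stream treefrogs come in two forms:
*long calls* (pulse trains; a call with more than three pulses after the
first rising peak) and *short calls* (three or fewer pulses).  Long calls
are further typed by their amplitude profile:

* Type 1 — a regular train of consecutive pulses with similar amplitude;
* Type 2 — a dominant onset peak, then an accelerating weak-to-strong
  pulse train, usually closed by a short terminal peak.

Short calls are summarised by five per-call parameters:

* DT — call duration, onset to offset;
* RT — rise time, onset to the highest envelope peak;
* FT — fall time, highest envelope peak to offset (DT = RT + FT);
* DF — dominant frequency, the peak of the power spectrum
  (1024-point FFT, Hann window);
* IQR — spectral interquartile range, the bandwidth between the first and
  third energy quartiles of the spectrum.

Per-individual call parameters are the arithmetic mean of 10 calls from the
same caller; individuals with fewer than 10 analyzable calls are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d
from scipy.stats import spearmanr

__all__ = [
    "CallRecording",
    "Pulse",
    "Call",
    "ShortCallFeatures",
    "SegmentConfig",
    "PulseConfig",
    "TypingConfig",
    "envelope",
    "segment_calls",
    "detect_pulses",
    "classify_call",
    "classify_long_type",
    "short_call_features",
    "individual_profile",
    "analyze_recording",
]

SHORT = "SHORT"
LONG = "LONG"
LONG_TYPE1 = "LONG_TYPE1"
LONG_TYPE2 = "LONG_TYPE2"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class CallRecording:
    """A mono waveform plus its recording metadata."""

    samples: np.ndarray
    rate: float
    individual_id: str = ""
    locality: str = ""
    region: str = ""
    temp_C: float = np.nan
    humidity_pct: float = np.nan

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")


@dataclass(frozen=True)
class Pulse:
    peak_time: float  # s, relative to recording start
    peak_amplitude: float  # envelope units


@dataclass
class Call:
    start_time: float
    end_time: float
    pulses: list[Pulse] = field(default_factory=list)
    call_type: str = UNCLASSIFIED
    flags: list[str] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class ShortCallFeatures:
    DT: float  # s
    RT: float  # s
    FT: float  # s
    DF: float  # Hz
    IQR: float  # Hz


@dataclass
class SegmentConfig:
    """Segmentation thresholds.

    The noise floor is 5x the median envelope of the whole recording, which
    presumes the recording is mostly between-call background; detected
    regions are then extended outward down to ``extend_mult`` x median so
    slow onsets/offsets are not clipped.  Sub-threshold gaps shorter than
    ``merge_gap_ms`` are merged, keeping a pulsed long call in one piece
    while splitting the calls of a bout.
    """

    smooth_ms: float = 2.0
    noise_floor_mult: float = 5.0
    extend_mult: float = 1.5
    merge_gap_ms: float = 50.0
    min_call_ms: float = 10.0


@dataclass
class PulseConfig:
    rel_threshold: float = 0.1  # fraction of in-call envelope peak
    min_gap_ms: float = 5.0
    prominence_frac: float = 0.05


@dataclass
class TypingConfig:
    """Long/short rule and Type 1 / Type 2 amplitude heuristics.

    The field rule leaves a call with exactly three pulses after the first
    rising peak unassigned; we classify it SHORT (long requires >= 4) and
    expose the cut as ``long_min_pulses_after_first``.  The Type 1 / Type 2
    thresholds are validated against the synthesizer.
    """

    long_min_pulses_after_first: int = 4
    count_excludes_first: bool = True
    onset_ratio: float = 1.5  # first pulse vs median mid-train amplitude
    trend_min: float = 0.5  # Spearman rho of mid-train amplitudes vs time
    cv_max: float = 0.25  # amplitude CV bound for Type 1


def envelope(samples: np.ndarray, rate: float, smooth_ms: float = 2.0) -> np.ndarray:
    """Moving-RMS amplitude envelope (window ``smooth_ms``).

    Non-negative, same length as the input, invariant under sign flip.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("empty input")
    if smooth_ms <= 0:
        raise ValueError("smooth_ms must be positive")
    win = max(1, int(round(smooth_ms * 1e-3 * rate)))
    ms = uniform_filter1d(samples * samples, size=win, mode="nearest")
    return np.sqrt(np.maximum(ms, 0.0))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def segment_calls(recording: CallRecording, cfg: SegmentConfig | None = None) -> list[Call]:
    """Segment a recording into calls (types unassigned).

    Calls are maximal regions where the envelope exceeds the noise floor,
    with short sub-threshold gaps merged; returned non-overlapping, ordered.
    A silent recording yields an empty list.
    """
    cfg = cfg or SegmentConfig()
    env = envelope(recording.samples, recording.rate, cfg.smooth_ms)
    med = float(np.median(env))
    if med == 0.0 and env.max() == 0.0:
        return []
    floor = cfg.noise_floor_mult * med
    if floor == 0.0:  # noiseless recording: fall back to a fraction of peak
        floor = 0.05 * float(env.max())
    mask = env > floor
    runs = _runs(mask)
    if not runs:
        return []

    merge_gap = int(round(cfg.merge_gap_ms * 1e-3 * recording.rate))
    merged: list[list[int]] = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    min_len = int(round(cfg.min_call_ms * 1e-3 * recording.rate))
    merged = [r for r in merged if r[1] - r[0] >= min_len]

    # hysteresis: grow each region down to the low threshold, without
    # running into the neighbouring region
    low = max(cfg.extend_mult * med, 1e-12)
    out: list[Call] = []
    for k, (a, b) in enumerate(merged):
        left_stop = merged[k - 1][1] if k > 0 else 0
        right_stop = merged[k + 1][0] if k + 1 < len(merged) else env.size
        while a > left_stop and env[a - 1] > low:
            a -= 1
        while b < right_stop and env[b] > low:
            b += 1
        out.append(Call(start_time=a / recording.rate, end_time=b / recording.rate))
    return out


def detect_pulses(
    call: Call,
    env: np.ndarray,
    rate: float,
    cfg: PulseConfig | None = None,
) -> list[Pulse]:
    """Detect envelope pulse peaks within a call.

    Pulses are local envelope maxima above ``rel_threshold`` x the in-call
    peak, separated by at least ``min_gap_ms``, ordered by time.
    """
    cfg = cfg or PulseConfig()
    a = int(round(call.start_time * rate))
    b = int(round(call.end_time * rate))
    if b <= a:
        raise ValueError("degenerate (zero-length) call")
    seg = env[a:b]
    peak = float(seg.max())
    if peak <= 0:
        return []
    distance = max(1, int(round(cfg.min_gap_ms * 1e-3 * rate)))
    locs, _ = sps.find_peaks(
        seg,
        height=cfg.rel_threshold * peak,
        distance=distance,
        prominence=cfg.prominence_frac * peak,
    )
    if locs.size == 0:
        # monotone or single-lobe envelope: take the maximum itself
        locs = np.array([int(np.argmax(seg))])
    return [Pulse(peak_time=(a + i) / rate, peak_amplitude=float(seg[i])) for i in locs]


def classify_call(call: Call, cfg: TypingConfig | None = None) -> str:
    """Long/short rule from the pulse count.

    Counting excludes the first rising peak (the first detected pulse);
    >= ``long_min_pulses_after_first`` subsequent pulses -> LONG, else SHORT.
    Zero detected pulses classify SHORT with a warning flag.
    """
    cfg = cfg or TypingConfig()
    n = len(call.pulses)
    if n == 0:
        call.flags.append("no_pulses")
        return SHORT
    if cfg.count_excludes_first:
        n -= 1
    return LONG if n >= cfg.long_min_pulses_after_first else SHORT


def classify_long_type(call: Call, cfg: TypingConfig | None = None) -> str:
    """Type a long call from its pulse-amplitude profile.

    Type 2 requires a dominant onset peak (first pulse >= ``onset_ratio`` x
    the median mid-train amplitude) together with a rising amplitude trend
    across the mid-train (Spearman rho > ``trend_min``).  Type 1 requires a
    flat train (amplitude CV < ``cv_max``).  Anything else is UNCLASSIFIED.
    """
    cfg = cfg or TypingConfig()
    amps = np.array([p.peak_amplitude for p in call.pulses], dtype=float)
    if amps.size < 4:
        raise ValueError("long-call typing requires at least 4 pulses")
    mid = amps[1:-1]
    onset_ok = amps[0] >= cfg.onset_ratio * float(np.median(mid))
    if onset_ok and mid.size >= 3:
        rho = spearmanr(np.arange(mid.size), mid).statistic
        if np.isfinite(rho) and rho > cfg.trend_min:
            return LONG_TYPE2
    cv = float(np.std(amps) / np.mean(amps)) if np.mean(amps) > 0 else np.inf
    if cv < cfg.cv_max:
        return LONG_TYPE1
    return UNCLASSIFIED


def short_call_features(
    call: Call,
    samples: np.ndarray,
    rate: float,
    smooth_ms: float = 2.0,
    nfft: int = 1024,
) -> ShortCallFeatures:
    """The five short-call parameters DT, RT, FT, DF, IQR.

    DF is the peak of the Welch-averaged power spectrum (1024-point Hann
    segments, 50% overlap); IQR is |F(Q3) - F(Q1)| where F(q) is the
    frequency below which fraction q of the in-call spectral energy lies.
    Calls shorter than one FFT segment are zero-padded (flagged).
    """
    a = int(round(call.start_time * rate))
    b = int(round(call.end_time * rate))
    if b - a < max(8, int(0.002 * rate)):
        raise ValueError("call too short to analyze")
    seg = np.asarray(samples[a:b], dtype=np.float64)

    env = envelope(seg, rate, smooth_ms)
    i_peak = int(np.argmax(env))
    dt = (b - a) / rate
    rt = i_peak / rate
    ft = dt - rt

    nperseg = min(nfft, seg.size)
    if seg.size < nfft:
        call.flags.append("short_fft_segment")
    freqs, pxx = sps.welch(
        seg,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nfft,
        detrend=False,
    )
    df = float(freqs[int(np.argmax(pxx))])

    cum = np.cumsum(pxx)
    total = cum[-1]
    if total <= 0:
        iqr = 0.0
    else:
        cum = cum / total
        q1 = float(np.interp(0.25, cum, freqs))
        q3 = float(np.interp(0.75, cum, freqs))
        iqr = abs(q3 - q1)
    return ShortCallFeatures(DT=dt, RT=rt, FT=ft, DF=df, IQR=iqr)


def individual_profile(features: list[ShortCallFeatures]) -> ShortCallFeatures | None:
    """Per-individual parameters: the mean of the first 10 analyzable calls.

    Individuals with fewer than 10 calls are excluded (returns None).
    """
    if len(features) < 10:
        return None
    sel = features[:10]
    return ShortCallFeatures(
        DT=float(np.mean([f.DT for f in sel])),
        RT=float(np.mean([f.RT for f in sel])),
        FT=float(np.mean([f.FT for f in sel])),
        DF=float(np.mean([f.DF for f in sel])),
        IQR=float(np.mean([f.IQR for f in sel])),
    )


def analyze_recording(
    recording: CallRecording,
    seg_cfg: SegmentConfig | None = None,
    pulse_cfg: PulseConfig | None = None,
    typing_cfg: TypingConfig | None = None,
) -> tuple[list[Call], pd.DataFrame]:
    """Segment, pulse-detect, and type every call in a recording.

    Returns the typed calls and a per-call feature table (short-call
    feature columns are NaN for long calls).
    """
    seg_cfg = seg_cfg or SegmentConfig()
    pulse_cfg = pulse_cfg or PulseConfig()
    typing_cfg = typing_cfg or TypingConfig()
    env = envelope(recording.samples, recording.rate, seg_cfg.smooth_ms)
    calls = segment_calls(recording, seg_cfg)
    rows = []
    for i, call in enumerate(calls):
        call.pulses = detect_pulses(call, env, recording.rate, pulse_cfg)
        kind = classify_call(call, typing_cfg)
        feats = None
        if kind == LONG:
            try:
                call.call_type = classify_long_type(call, typing_cfg)
            except ValueError:
                call.call_type = UNCLASSIFIED
        else:
            call.call_type = SHORT
            try:
                feats = short_call_features(call, recording.samples, recording.rate,
                                            smooth_ms=seg_cfg.smooth_ms)
            except ValueError:
                call.flags.append("unanalyzable_short_call")
        rows.append(
            {
                "individual_id": recording.individual_id,
                "locality": recording.locality,
                "region": recording.region,
                "call_index": i,
                "start_s": call.start_time,
                "end_s": call.end_time,
                "n_pulses": len(call.pulses),
                "call_type": call.call_type,
                "DT": feats.DT if feats else np.nan,
                "RT": feats.RT if feats else np.nan,
                "FT": feats.FT if feats else np.nan,
                "DF": feats.DF if feats else np.nan,
                "IQR": feats.IQR if feats else np.nan,
                "temp_C": recording.temp_C,
                "humidity_pct": recording.humidity_pct,
            }
        )
    return calls, pd.DataFrame(rows)
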