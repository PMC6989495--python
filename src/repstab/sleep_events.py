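"""Slow-oscillation and fast-spindle detection plus sleep macrostructure.

Detection follows the widely used amplitude/duration operationalisations:

* slow oscillations (SOs) — the signal is band-passed 0.5-4 Hz; every pair of
  consecutive positive-to-negative zero crossings bounding a negative then a
  positive half-wave is a candidate, accepted when the full-wave duration
  lies in [0.9, 2.0] s, the trough is at or below the amplitude criterion
  (default -40 uV) and the trough-to-peak amplitude reaches the
  peak-to-peak criterion (default 75 uV).  An adaptive mode keeps the top
  25% of duration-valid candidates by peak-to-peak amplitude instead.
* fast spindles (SPs) — the signal is band-passed 13-16 Hz; the RMS envelope
  (200-ms moving window) must exceed its per-channel mean + 1.5 SD for
  0.5-3.0 s.  The envelope-peak time is the spindle's reference time.

Both detectors are deterministic and run per channel; events are never
de-duplicated across channels because the coupling histogram pools
electrodes before normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Hypnogram",
    "SleepMacroStats",
    "SlowOscillation",
    "Spindle",
    "SODetectorConfig",
    "SpindleDetectorConfig",
    "sleep_macrostructure",
    "detect_slow_oscillations",
    "detect_spindles",
    "events_to_frame",
    "SO_CHANNELS",
    "SP_SITE_GROUPS",
]

#: default detection sites
SO_CHANNELS = ("F3", "F1", "Fz", "F2", "F4", "FC1", "FC2", "Cz")
SP_SITE_GROUPS = {
    "frontocentral": ("F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
                      "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"),
    "centroparietal": ("TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
                       "TP8", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"),
}


# --------------------------------------------------------------------------
# hypnogram / macrostructure

EPOCH_LEN_S = 30.0
STAGES = {"W", "N1", "N2", "N3", "R"}


@dataclass
class Hypnogram:
    """30-s sleep-stage sequence with lights-out/lights-on epoch indices."""

    stages: list[str]
    lights_off: int = 0
    lights_on: int | None = None  # exclusive; defaults to end of sequence

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("hypnogram must be non-empty")
        bad = set(self.stages) - STAGES
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.lights_on is None:
            self.lights_on = len(self.stages)
        if not (0 <= self.lights_off <= self.lights_on <= len(self.stages)):
            raise ValueError("need 0 <= lights_off <= lights_on <= n_epochs")

    def in_bed(self) -> list[str]:
        return self.stages[self.lights_off:self.lights_on]

    def stage_mask(self, stage: str, fs: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask of one stage (for stage-restricted detection)."""
        mask = np.zeros(n_samples, dtype=bool)
        spe = int(round(EPOCH_LEN_S * fs))
        for i, st in enumerate(self.stages):
            if st == stage:
                mask[i * spe:(i + 1) * spe] = True
        return mask


@dataclass
class SleepMacroStats:
    tst_min: float
    sol_min: float | None
    rem_latency_min: float | None
    stage_min: dict
    stage_pct: dict
    efficiency_pct: float


def sleep_macrostructure(h: Hypnogram) -> SleepMacroStats:
    """TST, latencies, stage durations/percentages and sleep efficiency.

    TST counts non-wake epochs between lights out and lights on; SOL is the
    time from lights out to the first N1 epoch; REM latency is the time from
    sleep onset to the first R epoch; efficiency is TST as a percentage of
    time in bed.  Latencies are ``None`` when the defining epoch never
    occurs.
    """
    bed = h.in_bed()
    epoch_min = EPOCH_LEN_S / 60.0
    tib = len(bed) * epoch_min
    tst = sum(1 for s in bed if s != "W") * epoch_min
    sol = next((i for i, s in enumerate(bed) if s == "N1"), None)
    sol_min = sol * epoch_min if sol is not None else None
    rem = next((i for i, s in enumerate(bed) if s == "R"), None)
    rem_latency = (rem * epoch_min - sol_min) if (rem is not None and sol_min is not None) else None
    stage_min = {st: sum(1 for s in bed if s == st) * epoch_min
                 for st in ("N1", "N2", "N3", "R")}
    stage_pct = {st: (100.0 * m / tst if tst > 0 else 0.0)
                 for st, m in stage_min.items()}
    eff = 100.0 * tst / tib if tib > 0 else 0.0
    return SleepMacroStats(tst_min=tst, sol_min=sol_min,
                           rem_latency_min=rem_latency, stage_min=stage_min,
                           stage_pct=stage_pct, efficiency_pct=eff)


# --------------------------------------------------------------------------
# event containers


@dataclass
class SlowOscillation:
    channel: str
    trough_time: float
    trough_amp: float       # microvolts, negative
    p2p_amp: float
    duration: float         # down-crossing to down-crossing, seconds
    peak_time: float = np.nan


@dataclass
class Spindle:
    channel: str
    onset: float
    offset: float
    peak_time: float        # envelope-peak time
    p2p_amp: float
    mean_freq: float
    site_group: str = ""
    trough_time: float = np.nan  # time of the band-signal minimum in the event

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events])


def match_event_times(planted, detected, tol: float) -> tuple[float, float]:
    """Greedy one-to-one matching of event times within ``tol`` seconds.

    Returns (recall, precision) of ``detected`` against ``planted``.
    """
    planted = np.sort(np.asarray(planted, dtype=float))
    detected = np.sort(np.asarray(detected, dtype=float))
    if planted.size == 0 or detected.size == 0:
        return 0.0, 0.0
    used = np.zeros(detected.size, dtype=bool)
    hits = 0
    for t in planted:
        d = np.abs(detected - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] < tol:
            used[j] = True
            hits += 1
    return hits / planted.size, used.sum() / detected.size


# --------------------------------------------------------------------------
# detectors


@dataclass
class SODetectorConfig:
    band: tuple[float, float] = (0.5, 4.0)
    duration_range: tuple[float, float] = (0.9, 2.0)
    trough_uv: float = -40.0        # trough must be <= this
    p2p_uv: float = 75.0            # trough-to-peak must be >= this
    adaptive_percentile: float | None = None  # e.g. 75 -> keep top 25% by p2p
    filter_order: int = 3


def _bandpass(data: np.ndarray, fs: float, band: tuple[float, float],
              order: int) -> np.ndarray:
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError(f"band {band} invalid for fs={fs}")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def detect_slow_oscillations(data: np.ndarray, fs: float, channels: list[str],
                             config: SODetectorConfig | None = None,
                             stage_mask: np.ndarray | None = None) -> list[SlowOscillation]:
    """Detect SOs per channel in (channels x samples) N3 EEG."""
    cfg = config or SODetectorConfig()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    filt = _bandpass(data, fs, cfg.band, cfg.filter_order)
    events: list[SlowOscillation] = []
    for ci, ch in enumerate(channels):
        x = filt[ci]
        neg = x < 0
        down = np.flatnonzero(~neg[:-1] & neg[1:]) + 1  # first sample below zero
        cands = []
        for a, b in zip(down[:-1], down[1:]):
            dur = (b - a) / fs
            if not (cfg.duration_range[0] <= dur <= cfg.duration_range[1]):
                continue
            seg = x[a:b]
            ti = int(np.argmin(seg))
            pi = int(np.argmax(seg))
            if pi <= ti:  # need negative half-wave before positive half-wave
                continue
            trough, peak = seg[ti], seg[pi]
            if trough >= 0 or peak <= 0:
                continue
            if stage_mask is not None and not stage_mask[a + ti]:
                continue
            cands.append(SlowOscillation(channel=ch, trough_time=(a + ti) / fs,
                                         trough_amp=float(trough),
                                         p2p_amp=float(peak - trough),
                                         duration=dur,
                                         peak_time=(a + pi) / fs))
        if cfg.adaptive_percentile is not None:
            if cands:
                thr = np.percentile([c.p2p_amp for c in cands], cfg.adaptive_percentile)
                cands = [c for c in cands if c.p2p_amp >= thr]
        else:
            cands = [c for c in cands
                     if c.trough_amp <= cfg.trough_uv and c.p2p_amp >= cfg.p2p_uv]
        events.extend(cands)
    events.sort(key=lambda e: (e.channel, e.trough_time))
    return events


@dataclass
class SpindleDetectorConfig:
    band: tuple[float, float] = (13.0, 16.0)
    envelope_window: float = 0.2    # s, RMS smoothing window
    threshold_sd: float = 1.5       # envelope > mean + k * SD
    duration_range: tuple[float, float] = (0.5, 3.0)
    filter_order: int = 4


def detect_spindles(data: np.ndarray, fs: float, channels: list[str],
                    site_group: str = "",
                    config: SpindleDetectorConfig | None = None,
                    stage_mask: np.ndarray | None = None) -> list[Spindle]:
    """Detect fast spindles per channel via a thresholded RMS envelope."""
    cfg = config or SpindleDetectorConfig()
    data = np.atleast_2d(np.asarray(data, dtype=float))
    win = int(round(cfg.envelope_window * fs))
    if data.shape[1] < 2 * win:
        raise ValueError("segment shorter than twice the envelope window")
    filt = _bandpass(data, fs, cfg.band, cfg.filter_order)
    kernel = np.ones(win) / win
    events: list[Spindle] = []
    for ci, ch in enumerate(channels):
        x = filt[ci]
        env = np.sqrt(np.convolve(x ** 2, kernel, mode="same"))
        thr = env.mean() + cfg.threshold_sd * env.std()
        above = env > thr
        if stage_mask is not None:
            above &= stage_mask
        edges = np.diff(above.astype(int))
        starts = np.flatnonzero(edges == 1) + 1
        stops = np.flatnonzero(edges == -1) + 1
        if above[0]:
            starts = np.r_[0, starts]
        if above[-1]:
            stops = np.r_[stops, len(above)]
        for s, e in zip(starts, stops):
            dur = (e - s) / fs
            if not (cfg.duration_range[0] <= dur <= cfg.duration_range[1]):
                continue
            seg = x[s:e]
            peak_idx = s + int(np.argmax(env[s:e]))
            # mean frequency from zero-crossing count of the band signal
            zc = int(np.sum(np.signbit(seg[:-1]) != np.signbit(seg[1:])))
            mean_freq = zc / (2.0 * dur) if dur > 0 else np.nan
            events.append(Spindle(channel=ch, onset=s / fs, offset=e / fs,
                                  peak_time=peak_idx / fs,
                                  p2p_amp=float(seg.max() - seg.min()),
                                  mean_freq=float(mean_freq),
                                  site_group=site_group,
                                  trough_time=(s + int(np.argmin(seg))) / fs))
    events.sort(key=lambda e: (e.channel, e.onset))
    return events
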