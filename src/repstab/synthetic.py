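"""Synthetic wake EEG, N3 sleep EEG and behavioural outcomes with ground truth.

The generator produces data with exactly the statistical structure the
analysis assumes, so every downstream stage has a parameter-recovery test:

* wake epochs — each paired associate owns a fixed region x sample template
  (band-limited 0.5-30 Hz Gaussian noise); repetition k of the item is
  ``sqrt(rho) * template + sqrt(1 - rho) * fresh_noise`` with rho the
  group's target stability, so the expected Pearson correlation between any
  two repetitions of the same item equals rho (each repetition correlates
  sqrt(rho) with the shared template).  Retrieval epochs mix the template at
  a latency-dependent template correlation m(t) (the early/late
  reinstatement levels): ``m * template + sqrt(1 - m^2) * noise``.
* N3 sleep — pink (1/f) background at 15 uV RMS plus slow oscillations
  (negative half-sine down-state, default -120 uV trough, followed by a
  half-amplitude positive half-sine up-state; full wave 1.0-1.5 s) at a
  configurable rate; each SO seeds fast-spindle bursts (13-16 Hz, Tukey
  envelope) whose centre offset from the SO trough is von Mises-distributed
  around the up-state (+0.45 s), concentration ``coupling_kappa``
  (0 = uniform over one SO cycle).
* outcomes — single-trial recognition drawn from a random-intercept logistic
  model with known coefficients.

One master seed; per-subject streams are derived deterministically from it,
so each subject is individually reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit

from .config import SimConfig
from .montage import REGIONS
from .preprocess import EpochSet

__all__ = [
    "GroundTruth",
    "SleepRecording",
    "simulate_wake_epochs",
    "simulate_sleep_eeg",
    "simulate_outcomes",
    "band_limited_noise",
    "so_waveform",
]

log = logging.getLogger(__name__)

#: kappa at or above this is treated as a point mass on the up-state
KAPPA_CAP = 1e6


@dataclass
class GroundTruth:
    """Planted parameters and events of one simulation."""

    stability: dict = field(default_factory=dict)          # subject -> rho
    so_events: pd.DataFrame | None = None                  # trough_time, duration, amplitude
    sp_events: pd.DataFrame | None = None                  # center_time, so_index, offset, freq
    linear_predictor: np.ndarray | None = None             # per-trial eta
    outcome_prob: np.ndarray | None = None
    random_intercepts: dict = field(default_factory=dict)  # subject -> u


@dataclass
class SleepRecording:
    """Continuous synthetic N3 recording plus hypnogram and ground truth."""

    data: np.ndarray            # channels x samples, microvolts
    fs: float
    channel_names: list[str]
    hypnogram: "Hypnogram"
    ground_truth: GroundTruth


def _subject_rng(master_seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-subject stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(stream,)))


def band_limited_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                       fs: float, low: float = 0.5, high: float = 30.0,
                       rms: float = 10.0) -> np.ndarray:
    """Gaussian noise band-limited to [low, high] Hz by spectral masking."""
    white = rng.standard_normal((n_rows, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    spec[:, (freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def pink_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
               rms: float = 15.0) -> np.ndarray:
    """1/f-amplitude noise (flat below 0.5 Hz to keep variance finite)."""
    white = rng.standard_normal((n_rows, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = 1.0 / np.sqrt(np.maximum(freqs, freqs[1] if n_samples > 1 else 1.0))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


# --------------------------------------------------------------------------
# wake epochs


def _retrieval_rho_profile(cfg: SimConfig) -> np.ndarray:
    """Per-sample encoding->retrieval correlation target."""
    t = np.arange(cfg.n_samples) / cfg.fs
    rho = np.zeros(cfg.n_samples)
    e0, e1 = cfg.early_window
    l0, l1 = cfg.late_window
    rho[(t >= e0) & (t < e1)] = cfg.reinstatement_early
    rho[(t >= l0) & (t < l1)] = cfg.reinstatement_late
    return rho


def simulate_wake_epochs(cfg: SimConfig, group_label: str,
                         rng_offset: int = 0) -> tuple[EpochSet, GroundTruth]:
    """Encoding + retrieval epochs for every subject of one group.

    Per subject: ``n_items * n_repetitions`` encoding epochs and ``n_items``
    retrieval (intact) epochs, each a regions x samples matrix.  Outcome
    metadata is left NA; :func:`simulate_outcomes` (or the pipeline) assigns
    it from the generating logistic model.
    """
    rho_enc = cfg.stability(group_label)
    n_sub = cfg.n_subjects_nsd if group_label == "NSD" else cfg.n_subjects_asr
    rho_ret = _retrieval_rho_profile(cfg)
    regions = list(REGIONS[: cfg.n_regions]) if cfg.n_regions <= len(REGIONS) \
        else [f"R{i}" for i in range(cfg.n_regions)]

    all_data, meta_rows = [], []
    gt = GroundTruth()
    for si in range(n_sub):
        subject = f"{group_label}{si + 1:02d}"
        rng = _subject_rng(cfg.seed, rng_offset + si)
        gt.stability[subject] = rho_enc
        templates = band_limited_noise(rng, cfg.n_items * cfg.n_regions,
                                       cfg.n_samples, cfg.fs).reshape(
            cfg.n_items, cfg.n_regions, cfg.n_samples)
        mix_enc = np.sqrt(rho_enc)  # rep-to-rep correlation = mix^2 = rho
        for item in range(cfg.n_items):
            for rep in range(1, cfg.n_repetitions + 1):
                noise = band_limited_noise(rng, cfg.n_regions, cfg.n_samples, cfg.fs)
                epoch = mix_enc * templates[item] + np.sqrt(1 - rho_enc) * noise
                all_data.append(epoch)
                meta_rows.append((subject, group_label, item, rep, "encoding",
                                  "intact", pd.NA))
            noise = band_limited_noise(rng, cfg.n_regions, cfg.n_samples, cfg.fs)
            epoch = rho_ret * templates[item] + np.sqrt(1 - rho_ret ** 2) * noise
            all_data.append(epoch)
            meta_rows.append((subject, group_label, item, 0, "retrieval",
                              "intact", pd.NA))
    meta = pd.DataFrame(meta_rows, columns=["subject", "group", "item",
                                            "repetition", "phase", "condition",
                                            "outcome"])
    epochs = EpochSet(data=np.stack(all_data), meta=meta, fs=cfg.fs,
                      row_names=regions, window=(0.0, cfg.epoch_len))
    return epochs, gt


# --------------------------------------------------------------------------
# sleep EEG

from .sleep_events import Hypnogram  # noqa: E402  (cycle-free: sleep_events does not import synthetic)


def so_waveform(fs: float, duration: float, trough_uv: float,
                upstate_ratio: float = 0.5,
                down_fraction: float = 0.3) -> tuple[np.ndarray, int]:
    """One slow-oscillation waveform and its trough sample index.

    Standard two-half-wave morphology: a brief negative half-sine
    (down-state, full trough amplitude, ``down_fraction`` of the full wave)
    followed by a broader positive half-sine (up-state) at ``upstate_ratio``
    of the trough amplitude.  The sharp down-state matches canonical SO
    shape and keeps the trough well localised against background noise; the
    steep zero crossings at the wave's ends make the full-wave duration read
    off the band-passed signal match the planted duration.
    """
    n = int(round(duration * fs))
    n1 = max(2, int(round(n * down_fraction)))
    t1 = np.arange(n1) / n1
    t2 = np.arange(n - n1) / (n - n1)
    wave = np.concatenate([
        trough_uv * np.sin(np.pi * t1),
        -trough_uv * upstate_ratio * np.sin(np.pi * t2),
    ])
    trough_idx = int(np.argmin(wave))
    return wave, trough_idx


def _spindle_burst(fs: float, duration: float, freq: float, amp_uv: float,
                   phase: float) -> np.ndarray:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = sps.windows.tukey(n, alpha=0.3)
    return amp_uv * env * np.sin(2 * np.pi * freq * t + phase)


DEFAULT_SLEEP_CHANNELS = ["F3", "Fz", "F4", "FC1", "FC2", "Cz", "CP1", "CPz", "CP2"]


def simulate_sleep_eeg(cfg: SimConfig, channels: list[str] | None = None,
                       rng_offset: int = 10_000,
                       kappa: float | None = None) -> SleepRecording:
    """Synthesize one subject's N3 sleep with planted SOs and nested spindles.

    Events are planted identically on every channel (synthetic SOs and
    spindles are widespread) over independent pink-noise backgrounds.
    ``kappa`` overrides ``cfg.coupling_kappa`` (used for per-group coupling).
    """
    kappa = cfg.coupling_kappa if kappa is None else kappa
    if kappa < 0:
        raise ValueError("coupling_kappa must be >= 0")
    channels = list(channels) if channels is not None else list(DEFAULT_SLEEP_CHANNELS)
    rng = _subject_rng(cfg.seed, rng_offset)
    fs = cfg.fs
    n_samples = int(round(cfg.sleep_minutes * 60 * fs))
    data = pink_noise(rng, len(channels), n_samples, rms=cfg.noise_rms_uv)

    # --- SO placement: refractory + exponential gap, mean interval 60/rate
    mean_iv = 60.0 / cfg.so_rate
    refractory = cfg.so_duration_range[1] + 0.5
    if mean_iv <= refractory:
        raise ValueError("so_rate too high for non-overlapping slow oscillations")
    margin = 3.5
    t, trough_times, durations, amps = margin, [], [], []
    while True:
        dur = rng.uniform(*cfg.so_duration_range)
        trough = t + dur * 0.15  # trough sits mid-way through the down half-wave
        if trough + dur > cfg.sleep_minutes * 60 - margin:
            break
        trough_times.append(trough)
        durations.append(dur)
        amps.append(cfg.so_trough_uv * rng.uniform(0.9, 1.1))
        t += refractory + rng.exponential(mean_iv - refractory)

    so_cycle = np.mean(cfg.so_duration_range)
    sp_rows = []
    for i, (trough, dur, amp) in enumerate(zip(trough_times, durations, amps)):
        wave, trough_idx = so_waveform(fs, dur, amp)
        start = int(round(trough * fs)) - trough_idx
        data[:, start:start + len(wave)] += wave
        n_sp = 1 if cfg.sp_per_so == 1.0 else rng.poisson(cfg.sp_per_so)
        for _ in range(n_sp):
            if kappa >= KAPPA_CAP:
                offset = cfg.upstate_offset
            else:
                theta = rng.vonmises(0.0, kappa)
                offset = cfg.upstate_offset + theta * so_cycle / (2 * np.pi)
            center = trough + offset
            freq = rng.uniform(*cfg.sp_band)
            burst = _spindle_burst(fs, cfg.sp_duration, freq,
                                   cfg.sp_amplitude_uv, rng.uniform(0, 2 * np.pi))
            s0 = int(round(center * fs)) - len(burst) // 2
            if s0 < 0 or s0 + len(burst) > n_samples:
                continue
            data[:, s0:s0 + len(burst)] += burst
            sp_rows.append((center, i, offset, freq))

    gt = GroundTruth(
        so_events=pd.DataFrame({"trough_time": trough_times,
                                "duration": durations,
                                "amplitude": amps}),
        sp_events=pd.DataFrame(sp_rows, columns=["center_time", "so_index",
                                                 "offset", "freq"]),
    )
    n_epochs = int(np.ceil(cfg.sleep_minutes * 60 / 30.0))
    hyp = Hypnogram(stages=["N3"] * n_epochs, lights_off=0, lights_on=n_epochs)
    return SleepRecording(data=data, fs=fs, channel_names=channels,
                          hypnogram=hyp, ground_truth=gt)


# --------------------------------------------------------------------------
# behavioural outcomes


def simulate_outcomes(cfg: SimConfig, predictors: pd.DataFrame,
                      rng_offset: int = 20_000) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw single-trial recognition outcomes from the generating logistic model.

    ``predictors`` needs a ``subject`` column plus one column per name in
    ``cfg.predictor_names`` (standardized).  Returns a copy with ``outcome``
    (1 = correct recognition) and ``outcome_label`` columns, and the ground
    truth (linear predictors, probabilities, random intercepts).
    """
    missing = [c for c in cfg.predictor_names if c not in predictors.columns]
    if missing:
        raise ValueError(f"predictor columns missing: {missing}")
    X = predictors[list(cfg.predictor_names)].to_numpy(dtype=float)
    mains = [c for c in cfg.predictor_names if ":" not in c]
    Xm = predictors[mains].to_numpy(dtype=float)
    mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
    if np.any(np.abs(mu) > 0.05) or np.any(np.abs(sd - 1) > 0.05):
        warnings.warn("main-effect predictors do not look standardized "
                      "(|mean|>0.05 or |sd-1|>0.05)", stacklevel=2)
    rng = _subject_rng(cfg.seed, rng_offset)
    subjects = predictors["subject"].to_numpy()
    uniq = pd.unique(subjects)
    u = {s: rng.normal(0.0, cfg.sigma_u) for s in uniq}
    beta = np.asarray(cfg.beta, dtype=float)
    eta = beta[0] + X @ beta[1:] + np.array([u[s] for s in subjects])
    p = expit(eta)
    y = rng.random(len(p)) < p
    out = predictors.copy()
    out["outcome"] = y.astype(int)
    out["outcome_label"] = np.where(y, "remembered", "forgotten")
    gt = GroundTruth(linear_predictor=eta, outcome_prob=p, random_intercepts=u)
    return out, gt
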