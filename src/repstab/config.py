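"""Study and simulation configuration objects.

``SimConfig`` collects every knob of the synthetic-data generator; its
defaults are the study conditions the analysis assumes (two arms of 13 and
14 subjects, 48 paired associates x 4 encoding repetitions, 250 Hz, six
scalp regions).  ``StudyConfig`` wraps a ``SimConfig`` together with the
analysis settings (window specs, detector configs, statistics settings,
model formula) consumed by :mod:`repstab.pipeline`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = ["SimConfig", "StudyConfig", "load_config", "save_config"]


@dataclass
class SimConfig:
    """Parameters of the synthetic wake/sleep/behaviour generator.

    Attributes
    ----------
    n_subjects_nsd, n_subjects_asr
        Group sizes of the normal-sleep-duration and acute-sleep-restriction
        arms.
    n_items, n_repetitions
        Paired associates per subject and encoding repetitions per item.
    fs, epoch_len, n_regions
        Sampling rate (Hz), epoch length (s) and number of scalp regions of
        the wake epochs.
    stability_nsd, stability_asr
        Target across-repetition pattern correlation (rho) per group, in
        [0, 1).
    reinstatement_early, reinstatement_late
        Encoding->retrieval template correlation inside the early
        (150-350 ms) and late (340-700 ms) latency ranges.
    sleep_minutes, so_rate, sp_per_so, coupling_kappa
        Minutes of N3 to synthesise, slow oscillations per minute, expected
        spindles per SO, and von Mises concentration of spindle timing
        around the SO up-state (0 = uniform over the SO cycle).
    so_trough_uv
        SO trough amplitude (negative, microvolts).
    so_duration_range
        Full-wave SO duration range in seconds (drawn uniformly per event).
    upstate_offset
        Centre of the SO up-state relative to the trough (s); spindle
        placement is referenced to it.
    sp_amplitude_uv, sp_duration, sp_band
        Spindle envelope peak amplitude (microvolts), burst duration (s) and
        frequency band (Hz).
    noise_rms_uv
        RMS of the pink (1/f) sleep background.
    beta
        Coefficients of the generating logistic model:
        (intercept, encoding-STPS, coupling, early STPS_E-R, late STPS_E-R,
        then any interaction terms, in the order of
        ``SimConfig.predictor_names``).
    sigma_u
        SD of the subject-level random intercepts.
    p_false_alarm
        Bernoulli rate of false alarms on rearranged recognition trials
        (used only for the behavioural table; the logistic model concerns
        intact pairs).
    """

    n_subjects_nsd: int = 13
    n_subjects_asr: int = 14
    n_items: int = 48
    n_repetitions: int = 4
    fs: float = 250.0
    epoch_len: float = 1.0
    n_regions: int = 6
    stability_nsd: float = 0.6
    stability_asr: float = 0.35
    reinstatement_early: float = 0.5
    reinstatement_late: float = 0.4
    early_window: tuple[float, float] = (0.15, 0.35)
    late_window: tuple[float, float] = (0.35, 0.70)
    sleep_minutes: float = 20.0
    so_rate: float = 5.0
    sp_per_so: float = 1.0
    coupling_kappa: float = 4.0
    #: optional ASR-specific concentration; setting it above coupling_kappa
    #: plants a negative stability -> coupling link across the two arms
    coupling_kappa_asr: float | None = None
    so_trough_uv: float = -120.0
    so_duration_range: tuple[float, float] = (1.0, 1.5)
    upstate_offset: float = 0.45
    sp_amplitude_uv: float = 25.0
    sp_duration: float = 1.0
    sp_band: tuple[float, float] = (13.0, 16.0)
    noise_rms_uv: float = 15.0
    beta: tuple[float, ...] = (0.2, 0.9, 0.3, 0.6, 0.5, -0.3, 0.4)
    sigma_u: float = 0.8
    p_false_alarm: float = 0.42
    seed: int = 0

    #: predictor order matched to ``beta[1:]``
    predictor_names: tuple[str, ...] = (
        "encoding_stps",
        "coupling",
        "stps_er_early",
        "stps_er_late",
        "coupling:stps_er_early",
        "coupling:stps_er_late",
    )

    def __post_init__(self) -> None:
        for name in ("fs", "epoch_len", "sleep_minutes", "so_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"SimConfig.{name} must be finite and > 0, got {v!r}")
        for name in (
            "stability_nsd",
            "stability_asr",
            "reinstatement_early",
            "reinstatement_late",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v < 1.0):
                raise ValueError(f"SimConfig.{name} must lie in [0, 1), got {v!r}")
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be >= 0")
        if self.coupling_kappa_asr is not None and self.coupling_kappa_asr < 0:
            raise ValueError("coupling_kappa_asr must be >= 0")
        if not all(np.isfinite(self.beta)):
            raise ValueError("beta coefficients must be finite")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if len(self.beta) != len(self.predictor_names) + 1:
            raise ValueError(
                "beta must have one intercept plus one coefficient per "
                f"predictor ({len(self.predictor_names) + 1} values), got "
                f"{len(self.beta)}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_len))

    def stability(self, group: str) -> float:
        if group == "NSD":
            return self.stability_nsd
        if group == "ASR":
            return self.stability_asr
        raise ValueError(f"unknown group {group!r} (expected 'NSD' or 'ASR')")


@dataclass
class StudyConfig:
    """End-to-end study settings consumed by :func:`repstab.pipeline.run_study`."""

    sim: SimConfig = field(default_factory=SimConfig)
    # STPS sliding-window scheme
    window_len: float = 0.2
    step: int = 1
    bin_len: float = 0.02
    # scalar-predictor extraction windows (s, post-onset)
    encoding_window: tuple[float, float] = (0.5, 0.8)
    # SO/SP detector settings (None -> module defaults)
    so_config: dict = field(default_factory=dict)
    sp_config: dict = field(default_factory=dict)
    # coupling: up-state interval relative to the SO trough (s); the
    # analysis requires an explicit choice
    upstate_interval: tuple[float, float] = (0.3, 0.7)
    # statistics
    threshold_p: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    # model formula: main effects + interactions added stepwise
    model_terms: Sequence[str] = (
        "encoding_stps",
        "coupling",
        "stps_er_early",
        "stps_er_late",
        "coupling:stps_er_early",
        "coupling:stps_er_late",
    )
    output_dir: str = "results/study"

    def config_hash(self) -> str:
        """Stable short hash stamped into every artifact."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sim_raw = raw.pop("sim", {})
    for key in ("so_duration_range", "sp_band", "beta", "predictor_names",
                "early_window", "late_window"):
        if key in sim_raw and isinstance(sim_raw[key], list):
            sim_raw[key] = tuple(sim_raw[key])
    sim = SimConfig(**sim_raw)
    for key in ("encoding_window", "upstate_interval", "model_terms"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return StudyConfig(sim=sim, **raw)
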