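"""SO-referenced spindle event-correlation histograms and coupling strength.

For every detected slow oscillation, the spindle reference times (envelope
peaks by default) falling within +-3 s of the SO trough are collected into
48-ms bins (125 bins over the 6-s window).  Per electrode, bin counts are
divided by the number of SOs and by the bin width, giving a spindle rate in
Hz, then mean-centred over bins (baseline correction); the centred rates are
finally averaged across the electrodes of the site group.  Coupling strength
is the mean centred rate inside an explicitly chosen up-state interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sleep_events import SlowOscillation, Spindle

__all__ = ["CouplingConfig", "CouplingHistogram", "event_correlation_histogram",
           "coupling_strength"]


@dataclass
class CouplingConfig:
    window: float = 3.0          # histogram spans +- window seconds
    bin_width: float = 0.048
    reference: str = "peak"      # spindle reference time: 'peak' or 'trough'


@dataclass
class CouplingHistogram:
    bin_edges: np.ndarray        # len n_bins + 1, seconds relative to SO trough
    raw_rate: np.ndarray         # electrodes x bins, Hz
    centered_rate: np.ndarray    # bins (electrode-averaged after mean-centering)
    electrodes: list[str]
    site_group: str
    n_sos: int
    n_sps: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site_group": self.site_group,
            "bin_center_s": self.bin_centers,
            "raw_rate_hz": self.raw_rate.mean(axis=0),
            "centered_rate": self.centered_rate,
        })


def event_correlation_histogram(sos: list[SlowOscillation],
                                sps: list[Spindle],
                                site_group: str = "",
                                config: CouplingConfig | None = None) -> CouplingHistogram:
    """SO-trough-referenced spindle rate histogram, pooled over electrodes.

    Spindles from every electrode of the site group are binned against all
    SO troughs; normalisation (per SO, per second) and mean-centering happen
    per electrode before averaging.
    """
    cfg = config or CouplingConfig()
    if not sos:
        raise ValueError("no slow oscillations: histogram undefined")
    n_bins = int(round(2 * cfg.window / cfg.bin_width))
    edges = -cfg.window + np.arange(n_bins + 1) * cfg.bin_width
    troughs = np.array([so.trough_time for so in sos])

    electrodes = sorted({sp.channel for sp in sps})
    if not electrodes:
        electrodes = ["(none)"]
    raw = np.zeros((len(electrodes), n_bins))
    n_binned = 0
    for ei, ch in enumerate(electrodes):
        if cfg.reference not in ("peak", "trough"):
            raise ValueError("reference must be 'peak' or 'trough'")
        times = np.array([
            (sp.peak_time if cfg.reference == "peak" else sp.trough_time)
            for sp in sps if sp.channel == ch
        ])
        if times.size == 0:
            continue
        # offsets of every spindle from every SO trough inside the window
        offsets = (times[None, :] - troughs[:, None]).ravel()
        offsets = offsets[(offsets >= edges[0]) & (offsets < edges[-1])]
        counts, _ = np.histogram(offsets, bins=edges)
        n_binned += int(counts.sum())
        raw[ei] = counts / len(troughs) / cfg.bin_width
    centered = raw - raw.mean(axis=1, keepdims=True)
    hist = CouplingHistogram(bin_edges=edges, raw_rate=raw,
                             centered_rate=centered.mean(axis=0),
                             electrodes=electrodes, site_group=site_group,
                             n_sos=len(troughs), n_sps=n_binned)
    return hist


def coupling_strength(hist: CouplingHistogram,
                      interval: tuple[float, float]) -> float:
    """Mean centred spindle rate over bins whose centres fall in ``interval``.

    ``interval`` is the up-state window relative to the SO trough (seconds)
    and must be supplied explicitly; it is the subject-level predictor
    "temporal grouping of spindles by the SO up-state".
    """
    t1, t2 = interval
    if not (hist.bin_edges[0] <= t1 < t2 <= hist.bin_edges[-1]):
        raise ValueError(f"interval {interval} outside histogram window")
    centers = hist.bin_centers
    mask = (centers >= t1) & (centers <= t2)
    if not mask.any():
        raise ValueError(f"interval {interval} contains no bin centres")
    return float(hist.centered_rate[mask].mean())
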