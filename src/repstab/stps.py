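"""Spatiotemporal pattern similarity (STPS) between EEG trials.

Similarity between two 1-s trials is computed per scalp region with a
200-ms (50-sample) sliding window advancing one sample at a time: each
window yields the Pearson correlation of the two single-region voltage
segments.  Window-wise correlations are Fisher-z transformed and averaged
inside consecutive 20-ms bins, which turns the 201 window positions of a
250-Hz epoch into 40 temporal bins.  Two trial pairings are analysed:

* encoding stability — repetitions k and k+1 of the same paired associate
  (contrasts rep1-2, rep2-3, rep3-4, kept separate, never averaged);
* encoding-retrieval similarity (STPS_E-R) — the 4th encoding presentation
  against the retrieval presentation of the same (intact) pair,
  same-latency windows paired bin-to-bin.

Pearson correlation makes every map invariant to per-trial amplitude and
offset by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import EpochSet

__all__ = [
    "STPSWindowSpec",
    "STPSMap",
    "sliding_window_similarity",
    "bin_and_fisher",
    "encoding_stability",
    "encoding_retrieval_similarity",
    "stack_maps",
]

log = logging.getLogger(__name__)

#: correlations are clipped to +-(1 - Z_CLIP_EPS) before atanh so maps stay finite
Z_CLIP_EPS = 1e-7


@dataclass
class STPSWindowSpec:
    """Sliding-window scheme: 200-ms windows, 1-sample steps, 20-ms bins."""

    window_len: float = 0.2
    step: int = 1
    bin_len: float = 0.02

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_len * fs))

    def windows_per_bin(self, fs: float) -> int:
        per = self.bin_len * fs / self.step
        if abs(per - round(per)) > 1e-9 or round(per) < 1:
            raise ValueError(
                f"bin_len {self.bin_len}s is not a positive multiple of "
                f"step/fs = {self.step / fs}s"
            )
        return int(round(per))

    def n_windows(self, fs: float, n_samples: int) -> int:
        w = self.window_samples(fs)
        if w > n_samples:
            raise ValueError("window longer than epoch")
        return (n_samples - w) // self.step + 1

    def n_bins(self, fs: float, n_samples: int) -> int:
        return self.n_windows(fs, n_samples) // self.windows_per_bin(fs)

    def bin_centers(self, fs: float, n_samples: int,
                    window_start: float = 0.0) -> np.ndarray:
        """Bin centres (s, epoch-relative): middle of the covered data span."""
        per = self.windows_per_bin(fs)
        w = self.window_samples(fs)
        starts = np.arange(self.n_bins(fs, n_samples)) * per * self.step
        # a bin spans windows [start, start + per); centre of covered samples
        centre_samp = starts + ((per - 1) * self.step + w) / 2.0
        return window_start + centre_samp / fs


@dataclass
class STPSMap:
    """Region x time-bin Fisher-z similarity map for one subject/contrast."""

    values: np.ndarray  # regions x bins
    bin_centers: np.ndarray
    regions: list[str]
    contrast: str
    outcome: str | None = None
    subject: object = None
    n_items: int = 0
    qc_zero_variance: int = 0  # windows scored 0 because a segment was flat

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ri, region in enumerate(self.regions):
            for bi, c in enumerate(self.bin_centers):
                rows.append((self.subject, self.contrast, self.outcome, region,
                             float(c), float(self.values[ri, bi])))
        return pd.DataFrame(rows, columns=["subject", "contrast", "outcome",
                                           "region", "bin_center_s", "z"])


def sliding_window_similarity(trial_a: np.ndarray, trial_b: np.ndarray,
                              spec: STPSWindowSpec, fs: float) -> np.ndarray:
    """Per-region, per-window Pearson r between two trials.

    Parameters are region x sample arrays of equal shape.  Windows with a
    zero-variance segment in either trial have undefined correlation and are
    scored 0 (logged); affine rescaling of either trial leaves the result
    unchanged.
    """
    a = np.asarray(trial_a, dtype=float)
    b = np.asarray(trial_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("trials must be equal-shape region x sample arrays")
    w = spec.window_samples(fs)
    if w < 3:
        raise ValueError("window must cover at least 3 samples")
    r, n_flat = _window_corr(a, b, w, spec.step)
    if n_flat:
        log.warning("sliding_window_similarity: %d zero-variance window(s) scored 0", n_flat)
    return r


def _window_corr(a: np.ndarray, b: np.ndarray, w: int, step: int):
    """Vectorised windowed Pearson correlation along the sample axis."""
    wa = sliding_window_view(a, w, axis=-1)[..., ::step, :]
    wb = sliding_window_view(b, w, axis=-1)[..., ::step, :]
    wa = wa - wa.mean(axis=-1, keepdims=True)
    wb = wb - wb.mean(axis=-1, keepdims=True)
    num = (wa * wb).sum(axis=-1)
    va = (wa ** 2).sum(axis=-1)
    vb = (wb ** 2).sum(axis=-1)
    denom = np.sqrt(va * vb)
    flat = denom <= 0
    n_flat = int(flat.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(flat, 0.0, num / np.where(flat, 1.0, denom))
    return np.clip(r, -1.0, 1.0), n_flat


def bin_and_fisher(r_map: np.ndarray, spec: STPSWindowSpec, fs: float) -> np.ndarray:
    """Group windows into 20-ms bins and average Fisher-z within each bin.

    Windows are grouped by start sample, ``windows_per_bin`` consecutive
    starts per bin (5 at 250 Hz); trailing windows that do not fill a bin
    are discarded, which maps the 201 windows of a 1-s epoch to 40 bins.
    """
    r_map = np.asarray(r_map, dtype=float)
    if np.any(np.abs(r_map) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    per = spec.windows_per_bin(fs)
    n_bins = r_map.shape[-1] // per
    trimmed = r_map[..., : n_bins * per]
    z = np.arctanh(np.clip(trimmed, -1 + Z_CLIP_EPS, 1 - Z_CLIP_EPS))
    return z.reshape(*z.shape[:-1], n_bins, per).mean(axis=-1)


def _per_subject_maps(epochs: EpochSet, pair_meta, contrast: str,
                      outcome_class: str | None, spec: STPSWindowSpec,
                      return_items: bool):
    """Shared driver for the two pairing schemes.

    ``pair_meta`` is a callable (subject_meta) -> list of (idx_a, idx_b, item)
    row-index pairs within the epoch set.
    """
    maps: list[STPSMap] = []
    item_rows: list[dict] = []
    centers = spec.bin_centers(epochs.fs, epochs.data.shape[-1], epochs.window[0])
    for subject, grp in epochs.meta.groupby("subject", sort=True):
        pairs = pair_meta(grp)
        if outcome_class is not None:
            pairs = [p for p in pairs if p[3] == outcome_class]
        if not pairs:
            log.warning("stps: subject %s has no item pairs for contrast %s "
                        "(outcome=%s); excluded", subject, contrast, outcome_class)
            continue
        a = epochs.data[[p[0] for p in pairs]]
        b = epochs.data[[p[1] for p in pairs]]
        r, n_flat = _window_corr(a, b, spec.window_samples(epochs.fs), spec.step)
        z_items = bin_and_fisher(r, spec, epochs.fs)  # items x R x bins
        maps.append(STPSMap(values=z_items.mean(axis=0), bin_centers=centers,
                            regions=list(epochs.row_names), contrast=contrast,
                            outcome=outcome_class, subject=subject,
                            n_items=len(pairs), qc_zero_variance=n_flat))
        if return_items:
            for (ia, ib, item, out), zi in zip(pairs, z_items):
                item_rows.append({"subject": subject, "item": item,
                                  "outcome": out, "contrast": contrast,
                                  "z_map": zi})
    if return_items:
        return maps, item_rows
    return maps


def encoding_stability(epochs: EpochSet, pair: tuple[int, int] = (3, 4),
                       outcome_class: str | None = None,
                       spec: STPSWindowSpec | None = None,
                       return_items: bool = False):
    """Across-repetition STPS maps, one per subject.

    ``pair`` names the repetition contrast (k, k+1).  Similarity is computed
    item-wise between the two repetitions of the same paired associate, then
    averaged across items; repetition contrasts are never pooled.
    """
    spec = spec or STPSWindowSpec()
    k, k1 = pair
    if k1 != k + 1:
        raise ValueError("pair must be consecutive repetitions (k, k+1)")

    def pairs_of(grp: pd.DataFrame):
        enc = grp[grp["phase"] == "encoding"]
        out = []
        for item, sub in enc.groupby("item"):
            ra = sub.index[sub["repetition"] == k]
            rb = sub.index[sub["repetition"] == k1]
            if len(ra) and len(rb):
                out.append((ra[0], rb[0], item, sub["outcome"].iloc[0]))
        return out

    return _per_subject_maps(epochs, pairs_of, f"rep{k}-{k1}", outcome_class,
                             spec, return_items)


def encoding_retrieval_similarity(epochs: EpochSet,
                                  outcome_class: str | None = None,
                                  spec: STPSWindowSpec | None = None,
                                  encoding_rep: int = 4,
                                  return_items: bool = False):
    """STPS_E-R maps: final encoding presentation vs retrieval of the same pair.

    Retrieval epochs are restricted to intact pairs; windows are paired at
    the same post-onset latency in both phases.
    """
    spec = spec or STPSWindowSpec()

    def pairs_of(grp: pd.DataFrame):
        enc = grp[(grp["phase"] == "encoding") & (grp["repetition"] == encoding_rep)]
        ret = grp[(grp["phase"] == "retrieval") & (grp["condition"] == "intact")]
        ret_by_item = {item: idx for idx, item in zip(ret.index, ret["item"])}
        out = []
        for idx, item, outc in zip(enc.index, enc["item"], enc["outcome"]):
            if item in ret_by_item:
                out.append((idx, ret_by_item[item], item, outc))
        return out

    return _per_subject_maps(epochs, pairs_of, f"enc{encoding_rep}-retrieval",
                             outcome_class, spec, return_items)


def stack_maps(maps: list[STPSMap]) -> tuple[np.ndarray, list]:
    """Stack per-subject maps into (subjects x regions x bins), with subject ids."""
    if not maps:
        raise ValueError("no maps to stack")
    values = np.stack([m.values for m in maps])
    return values, [m.subject for m in maps]
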