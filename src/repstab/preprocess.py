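"""EEG preprocessing: filtering, re-referencing, epoching, region averaging.

The chain mirrors a standard scalp-EEG similarity pipeline: common-average
re-reference, 0.5-30 Hz linear-phase FIR band-pass (Kaiser window, order
1326 at 250 Hz), 1-s epochs locked to stimulus onset, regional mean signals,
and outcome-class balancing (remembered vs forgotten trial counts matched
per subject by seeded subsampling).

Sample indexing is 0-based and all windows are half-open ``[start, stop)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import RegionMontage

__all__ = [
    "RawEEG",
    "EpochSet",
    "design_bandpass",
    "apply_zero_phase",
    "rereference_common_average",
    "epoch_by_events",
    "region_average",
    "match_trial_counts",
]

log = logging.getLogger(__name__)


@dataclass
class RawEEG:
    """Continuous multichannel recording (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    reference: str = "linked_mastoid"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RawEEG.data must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        if np.isnan(self.data).any():
            raise ValueError("RawEEG contains NaNs")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Epoched data: trials x rows x samples with aligned trial metadata.

    ``row_names`` are channel labels before region averaging and region
    labels after.  ``meta`` has one row per trial with at least the columns
    subject, group, item, repetition (1..4 for encoding, 0 for retrieval),
    phase ('encoding'|'retrieval'), condition ('intact'|'rearranged') and
    outcome ('remembered'|'forgotten' or NA before outcome assignment).
    """

    data: np.ndarray
    meta: pd.DataFrame
    fs: float
    row_names: list[str]
    window: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be trials x rows x samples")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("meta rows must match trial count")
        if self.data.shape[1] != len(self.row_names):
            raise ValueError("row_names must match data rows")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return replace(self, data=self.data[idx], meta=self.meta.iloc[idx].reset_index(drop=True))


# --------------------------------------------------------------------------
# filtering


def design_bandpass(fs: float, low: float, high: float, order: int = 1326,
                    atten_db: float = 60.0) -> np.ndarray:
    """Linear-phase Kaiser-window FIR band-pass taps (length ``order + 1``).

    The order must be large enough that the Kaiser transition band fits in
    the narrower of the two margins (``low`` on the left, ``fs/2 - high`` on
    the right); otherwise the band edges cannot be realised and the design
    is rejected.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"need 0 < low < high < fs/2, got low={low}, high={high}, fs={fs}")
    margin = min(low, fs / 2 - high)
    # Kaiser length estimate: N ~ (A - 7.95) / (2.285 * delta_omega),
    # checked at a 40 dB floor so that marginal but workable orders pass
    min_taps = int(np.ceil((40.0 - 7.95) / (2.285 * 2 * np.pi * margin / fs)))
    numtaps = order + 1
    if numtaps % 2 == 0:
        numtaps += 1  # type-I (odd length) for integer group delay
    if numtaps < min_taps:
        raise ValueError(
            f"order {order} too small for band {low}-{high} Hz at fs {fs}: "
            f"need at least {min_taps - 1}"
        )
    beta = sps.kaiser_beta(atten_db)
    return sps.firwin(numtaps, [low, high], window=("kaiser", beta),
                      pass_zero=False, fs=fs)


def apply_zero_phase(data: np.ndarray, taps: np.ndarray, axis: int = -1) -> np.ndarray:
    """Apply a linear-phase FIR forward once with group-delay compensation.

    For odd-length symmetric taps this is exactly 'same'-mode convolution,
    so the overall response is zero-phase without the squared magnitude
    response a forward-backward pass would give.
    """
    if len(taps) % 2 == 0:
        raise ValueError("taps must have odd length for exact delay compensation")
    data = np.asarray(data, dtype=float)
    n = data.shape[axis]
    pad = len(taps) // 2
    padded = np.concatenate(
        [np.zeros_like(np.take(data, range(pad), axis=axis)),
         data,
         np.zeros_like(np.take(data, range(pad), axis=axis))],
        axis=axis,
    ) if pad <= n else None
    if padded is None:
        # short segments: frequency-domain 'same' convolution handles them too
        return sps.fftconvolve(data, _shape_taps(taps, data.ndim, axis), mode="same", axes=axis)
    out = sps.fftconvolve(padded, _shape_taps(taps, data.ndim, axis), mode="valid", axes=axis)
    return out


def _shape_taps(taps: np.ndarray, ndim: int, axis: int) -> np.ndarray:
    shape = [1] * ndim
    shape[axis] = len(taps)
    return taps.reshape(shape)


def bandpass_raw(raw: RawEEG, low: float, high: float, order: int = 1326) -> RawEEG:
    taps = design_bandpass(raw.fs, low, high, order)
    return replace(raw, data=apply_zero_phase(raw.data, taps))


# --------------------------------------------------------------------------
# reference / epoching / regions


def rereference_common_average(raw: RawEEG) -> RawEEG:
    """Subtract the per-sample mean over channels (common average reference)."""
    if raw.data.shape[0] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = raw.data - raw.data.mean(axis=0, keepdims=True)
    return replace(raw, data=data, reference="common_average")


def epoch_by_events(raw: RawEEG, events: pd.DataFrame,
                    window: tuple[float, float] = (0.0, 1.0)) -> EpochSet:
    """Cut one epoch per event row.

    ``events`` must have an ``onset_s`` column; all other columns are carried
    into the epoch metadata.  Epochs spill over the recording edge are
    dropped with a logged count.
    """
    if "onset_s" not in events.columns:
        raise ValueError("events table needs an 'onset_s' column")
    start_off = int(round(window[0] * raw.fs))
    n_samp = int(round((window[1] - window[0]) * raw.fs))
    starts = np.round(events["onset_s"].to_numpy() * raw.fs).astype(int) + start_off
    ok = (starts >= 0) & (starts + n_samp <= raw.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("epoch_by_events: dropped %d event(s) outside the recording", n_dropped)
    starts = starts[ok]
    data = np.stack([raw.data[:, s:s + n_samp] for s in starts]) if len(starts) else \
        np.empty((0, raw.data.shape[0], n_samp))
    meta = events.loc[ok].drop(columns=["onset_s"]).reset_index(drop=True)
    es = EpochSet(data=data, meta=meta, fs=raw.fs, row_names=list(raw.channel_names),
                  window=window)
    es.n_dropped = n_dropped
    return es


def region_average(epochs: EpochSet, montage: RegionMontage) -> EpochSet:
    """Collapse channels to the unweighted mean trace of each region."""
    present = {ch: i for i, ch in enumerate(epochs.row_names)}
    region_rows = []
    for region in montage.regions:
        members = [present[ch] for ch in montage.channels_of(region) if ch in present]
        if not members:
            raise ValueError(f"region {region} has no mapped channel in the data")
        region_rows.append(epochs.data[:, members, :].mean(axis=1))
    data = np.stack(region_rows, axis=1)
    return replace(epochs, data=data, row_names=list(montage.regions))


def match_trial_counts(epochs: EpochSet, seed: int,
                       outcome_col: str = "outcome") -> EpochSet:
    """Balance remembered/forgotten counts per subject.

    The sampling unit is the paired associate: within each subject the items
    of the larger outcome class are randomly subsampled without replacement
    to the number of items in the smaller class, and every epoch of a
    retained item is kept (repetitions of one pair stay together).  When no
    ``item`` column exists, rows themselves are the unit.  Subjects with an
    empty class are excluded (flagged in ``excluded_subjects``) because an
    outcome contrast is undefined for them.
    """
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    excluded: list = []
    by_item = "item" in epochs.meta.columns
    for subject, grp in epochs.meta.groupby("subject", sort=True):
        if by_item:
            item_outcome = grp.groupby("item")[outcome_col].first()
            rem = item_outcome.index[item_outcome == "remembered"].to_numpy()
            forg = item_outcome.index[item_outcome == "forgotten"].to_numpy()
        else:
            rem = grp.index[grp[outcome_col] == "remembered"].to_numpy()
            forg = grp.index[grp[outcome_col] == "forgotten"].to_numpy()
        if len(rem) == 0 or len(forg) == 0:
            excluded.append(subject)
            continue
        n = min(len(rem), len(forg))
        chosen = np.concatenate([
            np.sort(rng.choice(rem, n, replace=False)),
            np.sort(rng.choice(forg, n, replace=False)),
        ])
        if by_item:
            keep.extend(grp.index[grp["item"].isin(chosen)])
        else:
            keep.extend(chosen)
    if excluded:
        log.warning("match_trial_counts: excluded subjects with an empty class: %s", excluded)
    out = epochs.select(np.sort(np.asarray(keep, dtype=int)))
    out.excluded_subjects = excluded
    return out
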