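"""Region montage: mapping from scalp electrodes to six analysis regions.

The pattern-similarity analysis operates on six regional mean signals
(left/right x frontal/central/parietal).  The default mapping partitions the
lateral channels of the extended 10-20 system; midline electrodes are left
unmapped by default because they cannot be assigned to a lateralised region
without an explicit choice.  Real montages override the default via a
two-column TSV (channel, region).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RegionMontage", "default_montage", "load_montage", "REGIONS"]

REGIONS = ("LF", "RF", "LC", "RC", "LP", "RP")

#: region adjacency: homologous left-right pairs plus anterior-posterior
#: chains within each hemisphere
_ADJACENCY = {
    "LF": {"RF", "LC"},
    "RF": {"LF", "RC"},
    "LC": {"RC", "LF", "LP"},
    "RC": {"LC", "RF", "RP"},
    "LP": {"RP", "LC"},
    "RP": {"LP", "RC"},
}

_DEFAULT_MAP = {
    "LF": ["Fp1", "AF3", "AF7", "F7", "F5", "F3", "F1", "FT7", "FC5", "FC3", "FC1"],
    "RF": ["Fp2", "AF4", "AF8", "F8", "F6", "F4", "F2", "FT8", "FC6", "FC4", "FC2"],
    "LC": ["T7", "C5", "C3", "C1", "TP7", "CP5", "CP3", "CP1"],
    "RC": ["T8", "C6", "C4", "C2", "TP8", "CP6", "CP4", "CP2"],
    "LP": ["P7", "P5", "P3", "P1", "PO7", "PO3", "O1"],
    "RP": ["P8", "P6", "P4", "P2", "PO8", "PO4", "O2"],
}


@dataclass
class RegionMontage:
    """Channel -> region mapping with a symmetric adjacency over regions."""

    mapping: dict[str, str]
    regions: tuple[str, ...] = REGIONS
    adjacency: dict[str, set[str]] = field(default_factory=lambda: {k: set(v) for k, v in _ADJACENCY.items()})

    def __post_init__(self) -> None:
        if len(self.regions) != 6:
            raise ValueError("exactly 6 regions are required")
        bad = set(self.mapping.values()) - set(self.regions)
        if bad:
            raise ValueError(f"mapping references unknown regions: {sorted(bad)}")
        for r, nbrs in self.adjacency.items():
            for n in nbrs:
                if r not in self.adjacency.get(n, set()):
                    raise ValueError(f"adjacency not symmetric: {r}-{n}")

    def channels_of(self, region: str) -> list[str]:
        return [ch for ch, r in self.mapping.items() if r == region]

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean region x region adjacency in ``self.regions`` order."""
        idx = {r: i for i, r in enumerate(self.regions)}
        mat = np.zeros((len(self.regions),) * 2, dtype=bool)
        for r, nbrs in self.adjacency.items():
            for n in nbrs:
                mat[idx[r], idx[n]] = mat[idx[n], idx[r]] = True
        return mat


def default_montage() -> RegionMontage:
    mapping = {ch: region for region, chans in _DEFAULT_MAP.items() for ch in chans}
    return RegionMontage(mapping=mapping)


def load_montage(path: str | Path) -> RegionMontage:
    """Read a channel->region TSV (columns: channel, region)."""
    tab = pd.read_csv(path, sep="\t")
    if not {"channel", "region"} <= set(tab.columns):
        raise ValueError("montage TSV needs 'channel' and 'region' columns")
    if tab["channel"].duplicated().any():
        dupes = tab.loc[tab["channel"].duplicated(), "channel"].tolist()
        raise ValueError(f"channels mapped more than once: {dupes}")
    return RegionMontage(mapping=dict(zip(tab["channel"], tab["region"])))
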