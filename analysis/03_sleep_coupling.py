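"""SO-spindle coupling during the recovery night and its link to encoding.

Detects slow oscillations and fast spindles in each subject's synthetic N3,
builds the SO-referenced spindle-rate histograms, summarises the up-state
coupling strength, and correlates it across subjects with the encoding
stability maps (cluster-level correlation test).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, study_config

from repstab.coupling import coupling_strength, event_correlation_histogram
from repstab.montage import default_montage
from repstab.sleep_events import (SO_CHANNELS, SP_SITE_GROUPS,
                                  detect_slow_oscillations, detect_spindles,
                                  sleep_macrostructure)
from repstab.stats import cluster_permutation
from repstab.stps import encoding_stability, stack_maps
from repstab.synthetic import DEFAULT_SLEEP_CHANNELS, simulate_sleep_eeg, simulate_wake_epochs
from repstab.preprocess import EpochSet


def main() -> None:
    cfg = study_config()
    channels = DEFAULT_SLEEP_CHANNELS
    so_chs = [c for c in channels if c in SO_CHANNELS]
    n_subjects = cfg.sim.n_subjects_nsd + cfg.sim.n_subjects_asr

    # subject ids in the same order the pipeline assigns sleep streams:
    # NSD01..NSD13 are streams 0..12, ASR01..ASR14 streams 13..26
    subject_ids = [f"NSD{i+1:02d}" for i in range(cfg.sim.n_subjects_nsd)] + \
                  [f"ASR{i+1:02d}" for i in range(cfg.sim.n_subjects_asr)]

    hist_rows, strengths = [], []
    for si, subject in enumerate(subject_ids):
        kappa = None
        if cfg.sim.coupling_kappa_asr is not None and subject.startswith("ASR"):
            kappa = cfg.sim.coupling_kappa_asr  # ASR arm couples more tightly
        rec = simulate_sleep_eeg(cfg.sim, channels=channels,
                                 rng_offset=10_000 + si, kappa=kappa)
        idx = {c: i for i, c in enumerate(channels)}
        sos = detect_slow_oscillations(rec.data[[idx[c] for c in so_chs]],
                                       rec.fs, so_chs)
        vals = []
        for site, site_chs in SP_SITE_GROUPS.items():
            chs = [c for c in channels if c in site_chs]
            sps = detect_spindles(rec.data[[idx[c] for c in chs]], rec.fs,
                                  chs, site)
            hist = event_correlation_histogram(sos, sps, site)
            vals.append(coupling_strength(hist, cfg.upstate_interval))
            f = hist.to_frame()
            f.insert(0, "subject", subject)
            hist_rows.append(f)
        macro = sleep_macrostructure(rec.hypnogram)
        strengths.append({"subject": subject, "coupling": float(np.mean(vals)),
                          "n_sos": len(sos) // len(so_chs),
                          "tst_min": macro.tst_min})

    strengths = pd.DataFrame(strengths)
    print(f"coupling strength (up-state {cfg.upstate_interval} s): "
          f"mean {strengths['coupling'].mean():.4f} Hz, "
          f"range [{strengths['coupling'].min():.4f}, "
          f"{strengths['coupling'].max():.4f}]")

    # correlate with encoding stability maps across subjects
    nsd, _ = simulate_wake_epochs(cfg.sim, "NSD", rng_offset=0)
    asr, _ = simulate_wake_epochs(cfg.sim, "ASR", rng_offset=1000)
    epochs = EpochSet(data=np.concatenate([nsd.data, asr.data]),
                      meta=pd.concat([nsd.meta, asr.meta], ignore_index=True),
                      fs=cfg.sim.fs, row_names=nsd.row_names, window=nsd.window)
    maps = encoding_stability(epochs, pair=(3, 4))
    values, map_subjects = stack_maps(maps)
    by_subject = dict(zip(strengths["subject"], strengths["coupling"]))
    covariate = np.array([by_subject[s] for s in map_subjects])
    res = cluster_permutation(values, "correlation",
                              default_montage().adjacency_matrix(),
                              threshold_p=cfg.threshold_p, n_perm=cfg.n_perm,
                              seed=cfg.seed, covariate=covariate)
    mean_r = float(np.nanmean(res.stat_map))
    top_p = res.clusters[0].p_corrected if res.clusters else float("nan")
    print(f"coupling vs encoding STPS: mean r = {mean_r:+.3f}, "
          f"top cluster corrected p = {top_p:.4f}")

    RESULTS.mkdir(exist_ok=True)
    pd.concat(hist_rows, ignore_index=True).to_csv(
        RESULTS / "coupling_histograms.tsv", sep="\t", index=False)
    strengths.to_csv(RESULTS / "coupling_strength.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
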