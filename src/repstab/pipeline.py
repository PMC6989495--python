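"""End-to-end study on synthetic (or user-supplied) data.

``run_study`` chains every stage: wake-epoch simulation for both arms ->
per-item pattern-similarity predictors -> N3 sleep synthesis, SO/SP
detection and coupling strength -> outcome generation from the known
logistic model -> remembered/forgotten balancing -> group STPS maps with
cluster permutation tests -> coupling-STPS correlation maps -> behavioural
table -> mixed-effects logistic fits.  Every artifact is stamped with the
config hash and seed, and each stage logs the counts a manual analysis
would QC (trials kept, events detected, subjects excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cpl
from . import model as mdl
from . import sleep_events as sev
from . import stats as st
from . import stps as stps_mod
from . import synthetic as syn
from .config import SimConfig, StudyConfig
from .montage import default_montage
from .preprocess import EpochSet, match_trial_counts

__all__ = ["run_study", "trial_predictor_table"]

log = logging.getLogger(__name__)


def _window_mean(z_map: np.ndarray, centers: np.ndarray,
                 window: tuple[float, float]) -> float:
    mask = (centers >= window[0]) & (centers <= window[1])
    return float(z_map[:, mask].mean())


def trial_predictor_table(epochs: EpochSet, coupling_by_subject: dict,
                          cfg: StudyConfig) -> pd.DataFrame:
    """One row per (subject, item) with the model's scalar predictors.

    encoding_stps: item-level mean Fisher-z in the configured encoding
    window (rep 3-4 contrast); stps_er_early/late: item-level STPS_E-R in
    the early/late latency windows; coupling: subject-level up-state
    coupling strength.  All predictors are standardized across trials.
    """
    spec = stps_mod.STPSWindowSpec(window_len=cfg.window_len, step=cfg.step,
                                   bin_len=cfg.bin_len)
    centers = spec.bin_centers(epochs.fs, epochs.data.shape[-1], epochs.window[0])
    _, enc_items = stps_mod.encoding_stability(
        epochs, pair=(cfg.sim.n_repetitions - 1, cfg.sim.n_repetitions),
        spec=spec, return_items=True)
    _, er_items = stps_mod.encoding_retrieval_similarity(
        epochs, spec=spec, encoding_rep=cfg.sim.n_repetitions, return_items=True)
    enc = {(d["subject"], d["item"]): _window_mean(d["z_map"], centers, cfg.encoding_window)
           for d in enc_items}
    er_early = {(d["subject"], d["item"]): _window_mean(d["z_map"], centers, cfg.sim.early_window)
                for d in er_items}
    er_late = {(d["subject"], d["item"]): _window_mean(d["z_map"], centers, cfg.sim.late_window)
               for d in er_items}
    keys = sorted(set(enc) & set(er_early))
    groups = dict(zip(epochs.meta["subject"], epochs.meta["group"]))
    table = pd.DataFrame({
        "subject": [k[0] for k in keys],
        "group": [groups[k[0]] for k in keys],
        "item": [k[1] for k in keys],
        "encoding_stps": [enc[k] for k in keys],
        "stps_er_early": [er_early[k] for k in keys],
        "stps_er_late": [er_late[k] for k in keys],
    })
    table["coupling"] = table["subject"].map(coupling_by_subject)
    table = mdl.standardize(table, ["encoding_stps", "coupling",
                                    "stps_er_early", "stps_er_late"])
    return table


def _sleep_stage(cfg: StudyConfig, subjects: list[str]) -> tuple[dict, dict, list]:
    """Simulate sleep, detect events, and summarise coupling per subject."""
    coupling_by_subject: dict[str, float] = {}
    histograms: dict[str, dict] = {}
    macro_rows = []
    so_cfg = sev.SODetectorConfig(**cfg.so_config) if cfg.so_config else sev.SODetectorConfig()
    sp_cfg = sev.SpindleDetectorConfig(**cfg.sp_config) if cfg.sp_config else sev.SpindleDetectorConfig()
    channels = syn.DEFAULT_SLEEP_CHANNELS
    so_chs = [c for c in channels if c in sev.SO_CHANNELS]
    site_channels = {
        site: [c for c in channels if c in chans]
        for site, chans in sev.SP_SITE_GROUPS.items()
    }
    for si, subject in enumerate(subjects):
        kappa = None
        if cfg.sim.coupling_kappa_asr is not None and subject.startswith("ASR"):
            kappa = cfg.sim.coupling_kappa_asr
        rec = syn.simulate_sleep_eeg(cfg.sim, channels=channels,
                                     rng_offset=10_000 + si, kappa=kappa)
        ch_idx = {c: i for i, c in enumerate(rec.channel_names)}
        sos = sev.detect_slow_oscillations(
            rec.data[[ch_idx[c] for c in so_chs]], rec.fs, so_chs, so_cfg)
        strengths = []
        hists = {}
        for site, chans in site_channels.items():
            if not chans:
                continue
            sps_ = sev.detect_spindles(rec.data[[ch_idx[c] for c in chans]],
                                       rec.fs, chans, site, sp_cfg)
            hist = cpl.event_correlation_histogram(sos, sps_, site)
            hists[site] = hist
            strengths.append(cpl.coupling_strength(hist, cfg.upstate_interval))
        coupling_by_subject[subject] = float(np.mean(strengths))
        histograms[subject] = hists
        macro = sev.sleep_macrostructure(rec.hypnogram)
        macro_rows.append({"subject": subject, "tst_min": macro.tst_min,
                           "n3_pct": macro.stage_pct["N3"],
                           "efficiency_pct": macro.efficiency_pct,
                           "n_sos": len(sos)})
        log.info("sleep stage %s: %d SOs, coupling %.4f", subject, len(sos),
                 coupling_by_subject[subject])
    return coupling_by_subject, histograms, macro_rows


def run_study(cfg: StudyConfig, write: bool = True) -> dict:
    """Run the full synthetic study; returns the report dict.

    Artifacts (TSV maps and tables, JSON report) go to ``cfg.output_dir``
    when ``write`` is true.
    """
    rng = np.random.default_rng(cfg.seed)
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    spec = stps_mod.STPSWindowSpec(window_len=cfg.window_len, step=cfg.step,
                                   bin_len=cfg.bin_len)
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}
    outdir = Path(cfg.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- stage 1: wake epochs
    nsd, gt_nsd = syn.simulate_wake_epochs(sim, "NSD", rng_offset=0)
    asr, gt_asr = syn.simulate_wake_epochs(sim, "ASR", rng_offset=1000)
    epochs = EpochSet(data=np.concatenate([nsd.data, asr.data]),
                      meta=pd.concat([nsd.meta, asr.meta], ignore_index=True),
                      fs=sim.fs, row_names=nsd.row_names, window=nsd.window)
    subjects = list(pd.unique(epochs.meta["subject"]))
    report["stages"]["wake"] = {"n_subjects": len(subjects),
                                "n_epochs": int(epochs.n_trials)}

    # --- stage 2: sleep, detection, coupling
    coupling_by_subject, histograms, macro_rows = _sleep_stage(cfg, subjects)
    report["stages"]["sleep"] = {"macrostructure": macro_rows}

    # --- stage 3: trial predictors and generated outcomes
    trials = trial_predictor_table(epochs, coupling_by_subject, cfg)
    for term in sim.predictor_names:
        if ":" in term and term not in trials.columns:
            a, b = term.split(":", 1)
            trials[term] = trials[a] * trials[b]
    trials, gt_out = syn.simulate_outcomes(sim, trials)
    trials["condition"] = "intact"
    # rearranged recognition trials (behavioural table only)
    rearr = trials[["subject", "group"]].copy()
    rearr["condition"] = "rearranged"
    rearr["outcome"] = (rng.random(len(rearr)) < sim.p_false_alarm).astype(int)
    behav = st.behavioral_summary(pd.concat([trials[["subject", "condition", "outcome"]],
                                             rearr[["subject", "condition", "outcome"]]],
                                            ignore_index=True))
    behav["group"] = behav["subject"].map(dict(zip(trials["subject"], trials["group"])))
    report["stages"]["behavior"] = {
        "hit_rate_by_group": behav.groupby("group")["hit_rate"].mean().to_dict(),
    }

    # --- stage 4: outcomes onto epochs, balanced remembered/forgotten sets
    key = dict(zip(zip(trials["subject"], trials["item"]), trials["outcome_label"]))
    epochs.meta["outcome"] = [key.get((s, i)) for s, i in
                              zip(epochs.meta["subject"], epochs.meta["item"])]
    balanced = match_trial_counts(epochs, seed=cfg.seed)
    report["stages"]["balance"] = {"n_epochs_kept": int(balanced.n_trials),
                                   "excluded_subjects": list(getattr(balanced, "excluded_subjects", []))}

    # --- stage 5: group STPS maps + cluster tests (remembered pairs)
    pair = (sim.n_repetitions - 1, sim.n_repetitions)
    enc_maps = stps_mod.encoding_stability(balanced, pair=pair,
                                           outcome_class="remembered", spec=spec)
    er_maps = stps_mod.encoding_retrieval_similarity(balanced,
                                                     outcome_class="remembered",
                                                     spec=spec)
    adjacency = default_montage().adjacency_matrix()[: sim.n_regions, : sim.n_regions]
    results_maps = {}
    for label, maps in (("encoding_stability", enc_maps),
                        ("encoding_retrieval", er_maps)):
        values, subs = stps_mod.stack_maps(maps)
        groups = np.array(["NSD" if s.startswith("NSD") else "ASR" for s in subs])
        cluster = st.cluster_permutation(values, "two_group", adjacency,
                                         threshold_p=cfg.threshold_p,
                                         n_perm=cfg.n_perm, seed=cfg.seed,
                                         groups=groups)
        cov = np.array([coupling_by_subject[s] for s in subs])
        corr = st.cluster_permutation(values, "correlation", adjacency,
                                      threshold_p=cfg.threshold_p,
                                      n_perm=cfg.n_perm, seed=cfg.seed,
                                      covariate=cov)
        mean_nsd = values[groups == "NSD"].mean()
        mean_asr = values[groups == "ASR"].mean()
        results_maps[label] = {
            "mean_z_nsd": float(mean_nsd),
            "mean_z_asr": float(mean_asr),
            "group_clusters": [_cluster_dict(c) for c in cluster.clusters[:5]],
            "coupling_corr_mean_r": float(np.nanmean(corr.stat_map)),
            "coupling_clusters": [_cluster_dict(c) for c in corr.clusters[:5]],
        }
        if write:
            frames = pd.concat([m.to_frame() for m in maps], ignore_index=True)
            frames.to_csv(outdir / f"stps_{label}.tsv", sep="\t", index=False)
    report["stages"]["maps"] = results_maps

    # --- stage 6: mixed-effects logistic models (early vs late STPS_E-R)
    models = {}
    for variant, er_term in (("early", "stps_er_early"), ("late", "stps_er_late")):
        terms = ["encoding_stps", "coupling", er_term, f"coupling:{er_term}"]
        fit = mdl.fit_random_intercept_logistic(trials, terms)
        models[variant] = {
            "terms": fit.terms, "aic": fit.aic, "loglik": fit.loglik,
            "sigma_u": fit.sigma_u, "n": fit.n_trials,
            "odds_ratios": dict(zip(["intercept"] + fit.terms,
                                    fit.odds_ratio.tolist())),
            "p_values": dict(zip(["intercept"] + fit.terms,
                                 fit.p_values.tolist())),
            "vif": fit.vif,
        }
    report["stages"]["model"] = models

    if write:
        behav.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
        trials.drop(columns=["outcome_label"]).to_csv(outdir / "trial_table.tsv",
                                                      sep="\t", index=False)
        hist_frames = []
        for subject, hists in histograms.items():
            for site, h in hists.items():
                f = h.to_frame()
                f.insert(0, "subject", subject)
                hist_frames.append(f)
        pd.concat(hist_frames, ignore_index=True).to_csv(
            outdir / "coupling_histograms.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _cluster_dict(c: st.Cluster) -> dict:
    return {"mass": c.mass, "p_corrected": c.p_corrected, "sign": c.sign,
            "n_cells": len(c.cells)}


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
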