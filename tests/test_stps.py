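"""Sliding-window pattern similarity: geometry, invariances, oracle parity."""

import numpy as np
import pandas as pd
import pytest

from repstab.preprocess import EpochSet
from repstab.stps import (STPSWindowSpec, bin_and_fisher,
                          encoding_retrieval_similarity, encoding_stability,
                          sliding_window_similarity, stack_maps)

SPEC = STPSWindowSpec()
FS = 250.0


def brute_force_stps(a: np.ndarray, b: np.ndarray, spec: STPSWindowSpec, fs: float):
    """Independent oracle: per-window np.corrcoef, then z-binning by loops."""
    w = spec.window_samples(fs)
    n_win = a.shape[1] - w + 1
    r = np.empty((a.shape[0], n_win))
    for reg in range(a.shape[0]):
        for s in range(n_win):
            r[reg, s] = np.corrcoef(a[reg, s:s + w], b[reg, s:s + w])[0, 1]
    per = spec.windows_per_bin(fs)
    n_bins = n_win // per
    z = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    out = np.empty((a.shape[0], n_bins))
    for bi in range(n_bins):
        out[:, bi] = z[:, bi * per:(bi + 1) * per].mean(axis=1)
    return r, out


class TestGeometry:
    def test_default_scheme_on_one_second_epoch(self):
        """1-s, 250-Hz epoch: 50-sample windows, 201 positions, 40 bins."""
        assert SPEC.window_samples(FS) == 50
        assert SPEC.n_windows(FS, 250) == 201
        assert SPEC.windows_per_bin(FS) == 5
        assert SPEC.n_bins(FS, 250) == 40

    def test_trailing_window_discarded(self, rng):
        a = rng.normal(size=(2, 250))
        b = rng.normal(size=(2, 250))
        r = sliding_window_similarity(a, b, SPEC, FS)
        assert r.shape == (2, 201)
        z = bin_and_fisher(r, SPEC, FS)
        assert z.shape == (2, 40)


class TestSimilarityValues:
    def test_affine_copy_gives_unit_correlation(self, rng):
        a = rng.normal(size=(3, 250))
        r = sliding_window_similarity(a, 2.0 * a + 7.0, SPEC, FS)
        np.testing.assert_allclose(r, 1.0, atol=1e-10)

    def test_sign_flip_gives_minus_one(self, rng):
        a = rng.normal(size=(3, 250))
        r = sliding_window_similarity(a, -a, SPEC, FS)
        np.testing.assert_allclose(r, -1.0, atol=1e-10)

    def test_four_sample_toy_window(self):
        spec = STPSWindowSpec(window_len=4 / FS, step=1, bin_len=4 / FS)
        a = np.array([[1.0, 2.0, 3.0, 4.0]])
        b = np.array([[1.0, 2.0, 3.0, 5.0]])
        r = sliding_window_similarity(a, b, spec, FS)
        expected = np.corrcoef(a[0], b[0])[0, 1]
        assert abs(expected - 0.9827) < 5e-4  # sanity on the frozen oracle value
        np.testing.assert_allclose(r[0, 0], expected, atol=1e-12)

    def test_symmetry_and_affine_map_invariance(self, rng):
        a = rng.normal(size=(6, 250))
        b = rng.normal(size=(6, 250))
        r_ab = sliding_window_similarity(a, b, SPEC, FS)
        r_ba = sliding_window_similarity(b, a, SPEC, FS)
        np.testing.assert_array_equal(r_ab, r_ba)
        r_scaled = sliding_window_similarity(0.3 * a - 11.0, b, SPEC, FS)
        np.testing.assert_allclose(r_ab, r_scaled, atol=1e-12)

    def test_zero_variance_window_scored_zero(self):
        a = np.zeros((1, 250))
        b = np.arange(250.0)[None, :]
        r = sliding_window_similarity(a, b, SPEC, FS)
        np.testing.assert_array_equal(r, 0.0)


class TestBinning:
    def test_all_zero_correlations_stay_zero(self):
        z = bin_and_fisher(np.zeros((6, 201)), SPEC, FS)
        np.testing.assert_array_equal(z, 0.0)

    def test_constant_half_correlation_bins_to_atanh(self):
        r = np.full((1, 200), 0.5)
        z = bin_and_fisher(r, SPEC, FS)
        np.testing.assert_allclose(z, np.arctanh(0.5), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_and_fisher(np.full((1, 201), 1.5), SPEC, FS)


class TestOracleEquivalence:
    def test_pipeline_matches_brute_force(self, rng):
        a = rng.normal(size=(6, 250))
        b = rng.normal(size=(6, 250))
        r_fast = sliding_window_similarity(a, b, SPEC, FS)
        z_fast = bin_and_fisher(r_fast, SPEC, FS)
        r_ref, z_ref = brute_force_stps(a, b, SPEC, FS)
        np.testing.assert_allclose(r_fast, r_ref, atol=1e-10)
        np.testing.assert_allclose(z_fast, z_ref, atol=1e-10)


def _epochs_from_arrays(per_item: dict, subject="s1") -> EpochSet:
    """Build an EpochSet from {(item, rep): array}; rep 0 marks retrieval."""
    data, rows = [], []
    for (item, rep), arr in per_item.items():
        data.append(arr)
        rows.append((subject, "NSD", item, rep,
                     "retrieval" if rep == 0 else "encoding", "intact",
                     "remembered"))
    meta = pd.DataFrame(rows, columns=["subject", "group", "item", "repetition",
                                       "phase", "condition", "outcome"])
    return EpochSet(data=np.stack(data), meta=meta, fs=FS, row_names=list("ABCDEF"))


class TestTrialPairings:
    def test_identical_repetitions_hit_the_z_ceiling(self, rng):
        arrs = {}
        for item in range(4):
            x = rng.normal(size=(6, 250))
            arrs[(item, 1)] = x
            arrs[(item, 2)] = x.copy()
        maps = encoding_stability(_epochs_from_arrays(arrs), pair=(1, 2))
        ceiling = np.arctanh(1 - 1e-7)
        np.testing.assert_allclose(maps[0].values, ceiling, rtol=1e-6)
        assert np.isfinite(maps[0].values).all()

    def test_item_shuffled_pairing_averages_to_zero(self, rng):
        """Pairing rep k with a different item's rep k+1 destroys similarity."""
        n_items = 30
        arrs = {}
        for item in range(n_items):
            arrs[(item, 1)] = rng.normal(size=(6, 250))
        for item in range(n_items):
            # rep 2 of item i is an unrelated trial (shifted item identity)
            arrs[(item, 2)] = rng.normal(size=(6, 250))
        maps = encoding_stability(_epochs_from_arrays(arrs), pair=(1, 2))
        se = 1.0 / np.sqrt(50 - 3) / np.sqrt(n_items)
        assert abs(maps[0].values.mean()) < 4 * se

    def test_retrieval_copy_of_final_encoding_hits_ceiling(self, rng):
        arrs = {}
        for item in range(3):
            x = rng.normal(size=(6, 250))
            arrs[(item, 4)] = x
            arrs[(item, 0)] = x.copy()
            arrs[(item, 1)] = rng.normal(size=(6, 250))
        maps = encoding_retrieval_similarity(_epochs_from_arrays(arrs))
        np.testing.assert_allclose(maps[0].values, np.arctanh(1 - 1e-7), rtol=1e-6)

    def test_group_stability_difference_recovered(self):
        """Higher generating stability must yield higher mean encoding STPS."""
        from repstab.config import SimConfig
        from repstab.synthetic import simulate_wake_epochs
        wins = 0
        n_rep = 10
        for seed in range(n_rep):
            hi_cfg = SimConfig(n_subjects_nsd=2, n_items=16, stability_nsd=0.6,
                               seed=seed)
            lo_cfg = SimConfig(n_subjects_nsd=2, n_items=16, stability_nsd=0.2,
                               seed=seed + 500)
            hi, _ = simulate_wake_epochs(hi_cfg, "NSD")
            lo, _ = simulate_wake_epochs(lo_cfg, "NSD")
            hi_maps = encoding_stability(hi, pair=(1, 2))
            lo_maps = encoding_stability(lo, pair=(1, 2))
            wins += stack_maps(hi_maps)[0].mean() > stack_maps(lo_maps)[0].mean()
        assert wins == n_rep

    def test_late_reinstatement_exceeds_early_when_planted(self):
        from repstab.config import SimConfig
        from repstab.synthetic import simulate_wake_epochs
        cfg = SimConfig(n_subjects_nsd=3, n_items=24, reinstatement_early=0.0,
                        reinstatement_late=0.6, seed=9)
        epochs, _ = simulate_wake_epochs(cfg, "NSD")
        maps = encoding_retrieval_similarity(epochs)
        values, _ = stack_maps(maps)
        centers = maps[0].bin_centers
        late = values[..., (centers >= 0.40) & (centers <= 0.65)].mean()
        early = values[..., centers <= 0.15].mean()
        assert late > early + 0.05


class TestNullCalibration:
    def test_independent_noise_trials_average_near_zero(self, rng):
        """Grand-mean z over bins for unrelated trials stays within 3 SE of 0."""
        n_pairs = 40
        zs = []
        for _ in range(n_pairs):
            a = rng.normal(size=(6, 250))
            b = rng.normal(size=(6, 250))
            zs.append(bin_and_fisher(sliding_window_similarity(a, b, SPEC, FS),
                                     SPEC, FS))
        zs = np.stack(zs)
        grand = zs.mean()
        se = zs.mean(axis=(1, 2)).std(ddof=1) / np.sqrt(n_pairs)
        assert abs(grand) < 3 * se + 1e-3
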