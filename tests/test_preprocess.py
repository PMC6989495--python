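"""Filtering, referencing, epoching, region averaging and trial balancing."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from repstab.montage import default_montage
from repstab.preprocess import (RawEEG, apply_zero_phase, design_bandpass,
                                epoch_by_events, match_trial_counts,
                                region_average, rereference_common_average)


class TestBandpassDesign:
    def test_frequency_response_meets_band_criteria(self):
        """0.5-30 Hz order-1326 design: <=1 dB ripple at 10 Hz, >=40 dB down at 40 Hz."""
        taps = design_bandpass(250.0, 0.5, 30.0, 1326)
        w, h = sps.freqz(taps, worN=[10.0, 40.0, 60.0], fs=250.0)
        gain_db = 20 * np.log10(np.abs(h))
        assert abs(gain_db[0]) <= 1.0
        assert gain_db[1] <= -40.0
        assert gain_db[2] <= -40.0

    def test_passband_sinusoid_preserved_stopband_killed(self):
        fs = 250.0
        taps = design_bandpass(fs, 0.5, 30.0, 1326)
        t = np.arange(int(20 * fs)) / fs
        mid = slice(int(5 * fs), int(15 * fs))
        ten = np.sin(2 * np.pi * 10 * t)
        out10 = apply_zero_phase(ten[None, :], taps)[0]
        assert abs(out10[mid].std() / ten[mid].std() - 1) < 0.01
        sixty = np.sin(2 * np.pi * 60 * t)
        out60 = apply_zero_phase(sixty[None, :], taps)[0]
        assert out60[mid].std() / sixty[mid].std() < 0.05

    def test_rejects_invalid_band_and_tiny_order(self):
        with pytest.raises(ValueError):
            design_bandpass(250.0, 30.0, 0.5, 1326)
        with pytest.raises(ValueError):
            design_bandpass(250.0, 0.5, 30.0, order=50)

    def test_zero_phase_keeps_symmetric_pulse_centred(self):
        """Group-delay compensated filtering must not shift a symmetric pulse."""
        fs = 250.0
        taps = design_bandpass(fs, 0.5, 30.0, 1326)
        n = int(16 * fs)
        x = np.zeros(n)
        centre = n // 2
        x[centre - 25:centre + 26] = np.hanning(51)
        y = apply_zero_phase(x[None, :], taps)[0]
        assert abs(int(np.argmax(y)) - centre) <= 1


class TestCommonAverage:
    def test_zero_mean_pair_unchanged_and_arithmetic(self):
        raw = RawEEG(np.array([[5.0, 10.0], [-5.0, 0.0]]), 250.0, ["a", "b"])
        out = rereference_common_average(raw)
        np.testing.assert_allclose(out.data[:, 0], [5.0, -5.0])
        np.testing.assert_allclose(out.data[:, 1], [5.0, -5.0])

    def test_column_sums_vanish_for_many_channels(self, rng):
        raw = RawEEG(rng.normal(0, 50, (59, 1000)), 250.0,
                     [f"ch{i}" for i in range(59)])
        out = rereference_common_average(raw)
        assert np.abs(out.data.sum(axis=0)).max() < 1e-9

    def test_single_channel_rejected(self):
        raw = RawEEG(np.zeros((1, 10)), 250.0, ["a"])
        with pytest.raises(ValueError):
            rereference_common_average(raw)


class TestEpoching:
    def _raw(self, n=10_000, n_ch=2, fs=250.0):
        data = np.arange(n_ch * n, dtype=float).reshape(n_ch, n)
        return RawEEG(data, fs, [f"ch{i}" for i in range(n_ch)])

    def test_half_open_indexing(self):
        raw = self._raw()
        ev = pd.DataFrame({"onset_s": [4.0], "item": [0]})
        es = epoch_by_events(raw, ev, window=(0.0, 1.0))
        np.testing.assert_array_equal(es.data[0, 0], raw.data[0, 1000:1250])
        assert es.data.shape == (1, 2, 250)

    def test_one_epoch_per_event(self):
        raw = self._raw(n=250 * 300)
        onsets = 1.0 + 1.2 * np.arange(192)
        ev = pd.DataFrame({"onset_s": onsets, "item": np.arange(192) % 48,
                           "repetition": np.arange(192) // 48 + 1})
        es = epoch_by_events(raw, ev)
        assert es.n_trials == 192
        assert list(es.meta.columns) == ["item", "repetition"]

    def test_event_outside_recording_dropped_with_count(self):
        raw = self._raw(n=2500)  # 10 s
        ev = pd.DataFrame({"onset_s": [1.0, 9.5], "item": [0, 1]})
        es = epoch_by_events(raw, ev)
        assert es.n_trials == 1
        assert es.n_dropped == 1


class TestRegionAverage:
    def test_single_pair_and_constant_channels(self):
        mont = default_montage()
        chans = ["F3", "F4", "C3", "C4", "P3", "P4", "F1", "F2"]
        data = np.zeros((1, 8, 10))
        data[0, chans.index("F3")] = 1.0   # LF members: F3, F1
        data[0, chans.index("F1")] = 3.0
        data[0, chans.index("C3")] = -2.0  # LC single member
        ev = pd.DataFrame({"subject": ["s"], "item": [0]})
        from repstab.preprocess import EpochSet
        es = EpochSet(data=data, meta=ev, fs=250.0, row_names=chans)
        out = region_average(es, mont)
        np.testing.assert_allclose(out.data[0, list(mont.regions).index("LF")], 2.0)
        np.testing.assert_allclose(out.data[0, list(mont.regions).index("LC")], -2.0)

    def test_opposite_channels_cancel(self):
        mont = default_montage()
        chans = ["F3", "F1", "F4", "F2", "C3", "C4", "P3", "P4"]
        data = np.random.default_rng(0).normal(size=(2, 8, 20))
        data[:, 1] = -data[:, 0]  # F1 = -F3 -> LF zero
        from repstab.preprocess import EpochSet
        es = EpochSet(data=data, meta=pd.DataFrame({"item": [0, 1]}), fs=250.0,
                      row_names=chans)
        out = region_average(es, mont)
        np.testing.assert_allclose(out.data[:, list(mont.regions).index("LF")], 0.0,
                                   atol=1e-12)

    def test_empty_region_rejected(self):
        mont = default_montage()
        from repstab.preprocess import EpochSet
        es = EpochSet(data=np.zeros((1, 2, 10)),
                      meta=pd.DataFrame({"item": [0]}), fs=250.0,
                      row_names=["F3", "F4"])
        with pytest.raises(ValueError):
            region_average(es, mont)

    def test_epoch_then_average_commutes_with_average_then_epoch(self, rng):
        """Region averaging and epoching are both linear selections: order-free."""
        mont = default_montage()
        chans = ["F3", "F1", "F4", "F2", "C3", "C4", "P3", "P4"]
        raw = RawEEG(rng.normal(size=(8, 5000)), 250.0, chans)
        ev = pd.DataFrame({"onset_s": [2.0, 5.0, 11.0], "item": [0, 1, 2]})
        a = region_average(epoch_by_events(raw, ev), mont)
        region_data = np.stack([
            raw.data[[chans.index(c) for c in mont.channels_of(reg) if c in chans]].mean(axis=0)
            for reg in mont.regions
        ])
        raw_regions = RawEEG(region_data, 250.0, list(mont.regions))
        b = epoch_by_events(raw_regions, ev)
        np.testing.assert_array_equal(a.data, b.data)


class TestMatchTrialCounts:
    def _epochs(self, n_rem, n_forg, seed=0):
        from repstab.preprocess import EpochSet
        n = n_rem + n_forg
        meta = pd.DataFrame({
            "subject": ["s1"] * n,
            "item": np.arange(n),
            "outcome": ["remembered"] * n_rem + ["forgotten"] * n_forg,
        })
        return EpochSet(data=np.zeros((n, 1, 4)), meta=meta, fs=250.0,
                        row_names=["LF"])

    @pytest.mark.parametrize("n_rem,n_forg,expect", [(30, 18, 36), (10, 10, 20)])
    def test_subsampled_to_smaller_class(self, n_rem, n_forg, expect):
        out = match_trial_counts(self._epochs(n_rem, n_forg), seed=1)
        assert out.n_trials == expect
        counts = out.meta["outcome"].value_counts()
        assert counts["remembered"] == counts["forgotten"]

    def test_equal_counts_unchanged(self):
        es = self._epochs(10, 10)
        out = match_trial_counts(es, seed=3)
        assert sorted(out.meta["item"]) == sorted(es.meta["item"])

    def test_same_seed_same_selection(self):
        es = self._epochs(25, 9)
        a = match_trial_counts(es, seed=42)
        b = match_trial_counts(es, seed=42)
        assert list(a.meta["item"]) == list(b.meta["item"])

    def test_empty_class_excludes_subject(self):
        es = self._epochs(5, 0)
        out = match_trial_counts(es, seed=0)
        assert out.n_trials == 0
        assert out.excluded_subjects == ["s1"]
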