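import numpy as np
import pytest

import whalehht as w
from whalehht.hilbert import find_grid_extremes
from whalehht.refgrids import HS1_CLASS_I, HS2_CLASS_II


def _central(x, frac=0.8):
    k = int(round((1 - frac) / 2 * x.size))
    return x[k : x.size - k]


class TestAnalyticTrack:
    def test_pure_tone_amplitude_and_frequency(self):
        t = np.arange(1000) / 1000.0
        a = 0.7
        track = w.analytic_track(a * np.sin(2 * np.pi * 50.0 * t), 1000.0)
        assert abs(np.median(_central(track.amplitude)) - a) < 0.01 * a
        assert abs(np.median(_central(track.inst_freq)) - 50.0) < 0.5

    def test_zero_signal_flagged_degenerate(self):
        track = w.analytic_track(np.zeros(100), 1000.0)
        assert track.degenerate
        assert np.all(track.amplitude == 0)
        assert np.all(track.inst_freq == 0)

    def test_linear_chirp_midpoint_frequency(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * (10.0 * t + 5.0 * t**2))  # 10 -> 20 Hz sweep
        track = w.analytic_track(x, 1000.0)
        assert abs(track.inst_freq[500] - 15.0) < 0.05 * 15.0

    def test_nonfinite_raises(self):
        x = np.ones(64)
        x[0] = np.inf
        with pytest.raises(ValueError):
            w.analytic_track(x, 1000.0)


class TestMarginalSpectrum:
    def test_tone_mass_concentrates_at_tone_frequency(self):
        t = np.arange(1000) / 1000.0
        x = np.sin(2 * np.pi * 50.0 * t)
        track = w.analytic_track(x, 1000.0)
        mf = w.marginal_spectrum(x, track, e_total=float(np.sum(x**2)))
        assert abs(mf.energy_ratio - 100.0) < 1e-6
        assert mf.values[49:52].sum() >= 95.0

    def test_zero_energy_component_gives_zero_spectrum(self):
        t = np.arange(1000) / 1000.0
        ref = np.sin(2 * np.pi * 30.0 * t)
        track = w.analytic_track(np.zeros(1000), 1000.0)
        mf = w.marginal_spectrum(np.zeros(1000), track, e_total=float(np.sum(ref**2)))
        assert np.all(mf.values == 0)

    def test_two_tone_energy_split_80_20(self):
        # components taken as known IMFs: amplitudes 1.0 and 0.5 -> 80/20 split
        t = np.arange(1000) / 1000.0
        imf1 = np.sin(2 * np.pi * 45.0 * t)
        imf2 = 0.5 * np.sin(2 * np.pi * 12.0 * t)
        e_total = float(np.sum(imf1**2) + np.sum(imf2**2))
        mf1 = w.marginal_spectrum(imf1, w.analytic_track(imf1, 1000.0), e_total)
        mf2 = w.marginal_spectrum(imf2, w.analytic_track(imf2, 1000.0), e_total)
        assert abs(mf1.argmax_freq - 45.0) <= 1.0
        assert abs(mf2.argmax_freq - 12.0) <= 1.0
        assert abs(mf1.energy_ratio - 80.0) < 0.5
        assert abs(mf2.energy_ratio - 20.0) < 0.5

    def test_mass_conservation_per_component(self, random_segment_corpus):
        for rec in random_segment_corpus[:8]:
            d = w.sift(rec.samples)
            prof = w.energy_profile(d)
            for i, imf in enumerate(d.imfs):
                mf = w.marginal_spectrum(
                    imf, w.analytic_track(imf, rec.rate), prof.e_total
                )
                assert mf.energy_ratio == pytest.approx(prof.ratios[i], rel=1e-6)

    @pytest.mark.parametrize("freq", [5.0, 12.0, 30.0, 45.0, 50.0])
    def test_tone_frequency_recovery(self, freq):
        rec = w.make_tones([w.ToneSpec(freq)], duration=1.0, rate=1000.0)
        d = w.sift(rec.samples)
        prof = w.energy_profile(d)
        mf = w.marginal_spectrum(
            d.imfs[0], w.analytic_track(d.imfs[0], 1000.0), prof.e_total
        )
        assert abs(mf.argmax_freq - freq) <= 1.0

    def test_invalid_e_total_raises(self):
        track = w.analytic_track(np.ones(64) * np.sin(np.arange(64)), 1000.0)
        with pytest.raises(ValueError):
            w.marginal_spectrum(np.ones(64), track, e_total=0.0)


class TestHilbertSpectrum:
    def _tone_grid(self, gate=None):
        t = np.arange(1323) / 7350.0
        x = np.sin(2 * np.pi * 45.0 * t)
        if gate is not None:
            x = np.where(t >= gate, x, 0.0)
        track = w.analytic_track(x, 7350.0)
        e = float(np.sum(x**2))
        return w.hilbert_spectrum(x, track, e, n_time_bins=6)

    def test_180ms_segment_has_six_30ms_columns(self):
        grid = self._tone_grid()
        assert grid.n_time_bins == 6
        # 1323 samples split 6 ways -> 220-sample bins, 29.93 ms nominal
        assert grid.time_bin_s == pytest.approx(0.030, abs=1e-3)
        assert grid.time_labels_ms.tolist() == [30, 60, 90, 120, 150, 180]

    def test_stationary_tone_spreads_mass_evenly(self):
        grid = self._tone_grid()
        per_bin = grid.values.sum(axis=1)[1:5]  # central bins, away from edges
        assert per_bin.max() <= 1.10 * per_bin.min()

    def test_gated_tone_mass_lands_late(self):
        grid = self._tone_grid(gate=0.120)  # tone on only in the last third
        late = grid.values[4:].sum()
        assert late >= 0.80 * grid.values.sum()

    def test_time_sum_reproduces_marginal(self, random_segment_corpus):
        for rec in random_segment_corpus[:6]:
            d = w.sift(rec.samples)
            prof = w.energy_profile(d)
            for i, imf in enumerate(d.imfs):
                track = w.analytic_track(imf, rec.rate)
                mf = w.marginal_spectrum(imf, track, prof.e_total)
                grid = w.hilbert_spectrum(imf, track, prof.e_total, n_time_bins=6)
                np.testing.assert_allclose(
                    grid.values.sum(axis=0), mf.values, rtol=1e-6, atol=1e-12
                )

    def test_invalid_bin_count_raises(self):
        t = np.arange(128) / 1000.0
        x = np.sin(2 * np.pi * 45.0 * t)
        with pytest.raises(ValueError):
            w.hilbert_spectrum(x, w.analytic_track(x, 1000.0), 1.0, n_time_bins=0)


class TestFindGridExtremes:
    def test_class1_first_imf_reference_grid(self):
        e = HS1_CLASS_I.extremes()
        assert (e.max_value, e.max_time, e.max_freq) == (5.3772, 30.0, 41.0)
        assert (e.second_value, e.second_time, e.second_freq) == (5.3723, 90.0, 42.0)

    def test_class2_second_imf_reference_grid(self):
        e = HS2_CLASS_II.extremes()
        assert (e.max_value, e.max_time, e.max_freq) == (6.9196, 90.0, 12.0)
        assert (e.second_value, e.second_time, e.second_freq) == (4.1130, 90.0, 11.0)

    def test_all_equal_grid_ties_break_to_first_cell(self):
        e = find_grid_extremes(np.ones((3, 4)))
        assert (e.max_time, e.max_freq) == (0.0, 0.0)
        assert (e.second_time, e.second_freq) == (0.0, 1.0)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            find_grid_extremes(np.zeros((0, 3)))
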