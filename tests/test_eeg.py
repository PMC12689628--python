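"""EEG/EMG chain: filtering, epoch spectra, rebinning, scoring,
architecture, normalizations, band power, and the SWA timecourse."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from sleepedit import (
    BANDS, BandDef, BinnedSpectra, Hypnogram, RawSpectra, Recording,
    architecture, band_power, epoch_psd, normalize_cross_state,
    normalize_within_state, preprocess, rebin, score, swa_timecourse,
)
from sleepedit.eeg import default_bin_labels


def _recording(eeg, fs=128.0, emg=None, start_zt=0.0):
    eeg = np.asarray(eeg, float)
    emg = np.zeros_like(eeg) if emg is None else np.asarray(emg, float)
    return Recording(eeg={"parietal": eeg, "frontal": eeg.copy()}, emg=emg,
                     fs=fs, start_zt=start_zt)


class TestPreprocess:
    def test_dc_removed_by_highpass(self):
        rec = _recording(np.full(512 * 20, 5.0), fs=512)
        out = preprocess(rec)
        assert abs(out.eeg["parietal"].mean()) < 1e-6 * 5.0

    def test_decimation_512_to_128_quarters_length(self):
        rec = _recording(np.random.default_rng(0).standard_normal(512 * 8),
                         fs=512)
        out = preprocess(rec, fs_out=128)
        assert out.fs == 128
        assert len(out.eeg["parietal"]) == 512 * 8 // 4

    def test_stopband_tone_attenuated_per_transfer_function(self):
        fs = 512.0
        t = np.arange(int(fs * 20)) / fs
        rec = _recording(np.sin(2 * np.pi * 60 * t) + np.sin(2 * np.pi * 10 * t),
                         fs=fs)
        out = preprocess(rec, fs_out=128)
        f, pxx = sps.periodogram(out.eeg["parietal"], fs=128)
        p60 = pxx[np.argmin(abs(f - 60))] if f.max() >= 60 else 0.0
        p10 = pxx[np.argmin(abs(f - 10))]
        # oracle: |H|^2 of the designed Butterworth, squared again for
        # forward-backward application
        sos = sps.butter(4, (0.1, 48.0), btype="bandpass", fs=fs, output="sos")
        _, h60 = sps.sosfreqz(sos, worN=[60.0], fs=fs)
        theo = abs(h60[0]) ** 4
        # 60 Hz is above the 64 Hz Nyquist after decimation; its residual
        # power must be below the designed stop-band response
        assert p60 <= max(theo * p10 * 10, 1e-12)
        assert p10 > 1.0  # passband tone survives

    def test_bad_rates_rejected(self):
        rec = _recording(np.zeros(512 * 4), fs=512)
        with pytest.raises(ValueError, match="divide"):
            preprocess(rec, fs_out=100)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(_recording(np.zeros(80), fs=80), fs_out=80)


class TestEpochPsd:
    def test_zero_signal_gives_zero_spectra(self):
        spec = epoch_psd(_recording(np.zeros(512 * 5)))
        assert spec.power.shape == (5, 257)
        assert np.all(spec.power == 0)
        assert np.allclose(np.diff(spec.freqs), 0.25)

    def test_partial_trailing_epoch_dropped(self):
        spec = epoch_psd(_recording(np.ones(512 * 3 + 100)))
        assert spec.power.shape[0] == 3

    def test_white_noise_satisfies_parseval(self):
        x = np.random.default_rng(1).standard_normal(512 * 1000)
        spec = epoch_psd(_recording(x))
        total = (spec.power.sum(axis=1) * 0.25).mean()
        assert total == pytest.approx(1.0, rel=0.05)

    def test_pure_tone_power_lands_in_its_quarter_bins(self):
        t = np.arange(512 * 50) / 128.0
        spec = epoch_psd(_recording(np.sin(2 * np.pi * 4.0 * t)))
        band = (spec.freqs >= 3.75) & (spec.freqs <= 4.25)
        frac = spec.power[:, band].sum() / spec.power.sum()
        assert frac >= 0.95

    def test_wrong_rate_directs_to_preprocess(self):
        with pytest.raises(ValueError, match="preprocess"):
            epoch_psd(_recording(np.zeros(512 * 2), fs=256))


class TestRebin:
    def test_bin_labels_follow_hybrid_scheme(self):
        labels = default_bin_labels()
        assert len(labels) == 30
        assert np.allclose(labels[:10], np.arange(0.5, 5.01, 0.5))
        assert np.allclose(labels[10:], np.arange(6, 26))

    def test_constant_spectrum_maps_to_constant_bins(self):
        freqs = np.arange(0, 257) * 0.25
        raw = RawSpectra(freqs=freqs, power=np.full((3, 257), 4.2))
        out = rebin(raw)
        assert np.allclose(out.power, 4.2)

    def test_each_bin_is_mean_of_its_quarter_bins(self):
        rng = np.random.default_rng(2)
        freqs = np.arange(0, 257) * 0.25
        raw = RawSpectra(freqs=freqs, power=rng.random((10, 257)))
        out = rebin(raw)
        for j, lab in enumerate(out.bin_labels):
            width = 0.5 if lab <= 5.0 else 1.0
            members = [int(round((lab - k * 0.25) / 0.25))
                       for k in range(int(width / 0.25))]
            expected = raw.power[:, members].mean(axis=1)
            assert np.allclose(out.power[:, j], expected)

    def test_mean_power_conserved_over_covered_range(self):
        rng = np.random.default_rng(3)
        freqs = np.arange(0, 257) * 0.25
        raw = RawSpectra(freqs=freqs, power=rng.random((5, 257)))
        out = rebin(raw)
        widths = np.where(out.bin_labels <= 5.0, 0.5, 1.0)
        integral_out = (out.power * widths).sum(axis=1)
        covered = (freqs >= 0.25) & (freqs <= 25.0)
        integral_in = (raw.power[:, covered] * 0.25).sum(axis=1)
        assert np.allclose(integral_out, integral_in)

    def test_wrong_resolution_rejected(self):
        raw = RawSpectra(freqs=np.arange(0, 26, 0.5),
                         power=np.ones((2, 52)))
        with pytest.raises(ValueError, match="0.25 Hz"):
            rebin(raw)


def _tone_epochs(specs, fs=128.0):
    """Build per-epoch signals from (delta_amp, theta_amp, emg_level) specs.

    With a 3 Hz delta tone and a 7 Hz theta tone the scorer's band-mean
    theta/delta ratio is exactly (theta_amp/delta_amp)^2.
    """
    n = int(4 * fs)
    t = np.arange(n) / fs
    eeg, emg = [], []
    for ad, at, em in specs:
        eeg.append(ad * np.sin(2 * np.pi * 3.0 * t)
                   + at * np.sin(2 * np.pi * 7.0 * t))
        emg.append(np.full(n, em))
    return _recording(np.concatenate(eeg), fs=fs, emg=np.concatenate(emg))


class TestScore:
    def test_rule_outcomes_on_constructed_epochs(self):
        trem_at = 10.0 * np.sqrt(1.4)  # ratio 1.4: mixed slow-wave/theta
        rec = _tone_epochs([
            (10.0, 2.0, 1.0),      # slow-wave dominant -> NREM
            (10.0, 2.0, 1.0),
            (2.0, 10.0, 1.0),      # theta dominant -> REM
            (10.0, trem_at, 1.0),  # mixed -> transition to REM
            (10.0, 2.0, 3.0),      # high EMG tone -> WAKE regardless of EEG
            (10.0, 2.0, 1.0),
            (2.0, 10.0, 1.0),
        ])
        hyp = score(rec)
        assert list(hyp.states) == ["NREM", "NREM", "REM", "TREM", "WAKE",
                                    "NREM", "REM"]

    def test_recovers_generating_hypnogram(self, short_recording):
        rec, hyp = short_recording
        scored = score(rec)
        assert (scored.states == hyp.states).mean() >= 0.90

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="one epoch"):
            score(_recording(np.zeros(100)))


class TestArchitecture:
    def test_all_nrem_day(self):
        hyp = Hypnogram.from_states(["NREM"] * 21600)
        summ = architecture(hyp)
        assert (summ.state_minutes["NREM"] == 720).all()
        assert summ.sleep_minutes.sum() == 1440
        assert summ.percent_sleep_in_light == pytest.approx(50.0)

    def test_trem_counts_into_rem_totals(self):
        states = ["REM"] * 100 + ["TREM"] * 20 + ["WAKE"] * 100
        summ = architecture(Hypnogram.from_states(states))
        assert summ.rem_total_minutes.sum() == pytest.approx(120 * 4 / 60.0)

    def test_totals_match_counting_oracle(self):
        rng = np.random.default_rng(4)
        states = rng.choice(["WAKE", "NREM", "REM", "TREM"], size=30000)
        hyp = Hypnogram.from_states(states)
        summ = architecture(hyp)
        for (day, phase), row in summ.state_minutes.iterrows():
            sel = (hyp.day_index == day) & (hyp.phase == phase)
            for s in ("WAKE", "NREM", "REM", "TREM"):
                assert row[s] == pytest.approx(
                    ((hyp.states == s) & sel).sum() * 4 / 60.0)

    def test_phase_minutes_sum_to_phase_length(self):
        hyp = Hypnogram.from_states(
            np.random.default_rng(5).choice(["WAKE", "NREM"], 21600))
        summ = architecture(hyp)
        assert np.allclose(summ.state_minutes.sum(axis=1), 720.0)


def _random_spec_and_hyp(seed, n_epochs=1200, start_zt=11.0):
    rng = np.random.default_rng(seed)
    power = rng.random((n_epochs, 30)) + 0.05
    spec = BinnedSpectra(power=power)
    states = rng.choice(["WAKE", "NREM", "REM", "TREM"], size=n_epochs,
                        p=[0.4, 0.4, 0.15, 0.05])
    hyp = Hypnogram.from_states(states, start_zt=start_zt)
    return spec, hyp


class TestNormalizations:
    def test_cross_state_identity_on_reference_window(self):
        spec, hyp = _random_spec_and_hyp(6)
        norm = normalize_cross_state(spec, hyp, phase="light", day=0)
        assert np.allclose(norm.sum(axis=0), 100.0)

    def test_cross_state_scale_invariance(self):
        spec, hyp = _random_spec_and_hyp(7)
        a = normalize_cross_state(spec, hyp, phase="dark", day=0)
        scaled = BinnedSpectra(power=spec.power * 37.5)
        b = normalize_cross_state(scaled, hyp, phase="dark", day=0)
        assert np.allclose(a.values, b.values)

    def test_cross_state_matches_direct_formula_oracle(self):
        spec, hyp = _random_spec_and_hyp(8)
        norm = normalize_cross_state(spec, hyp, phase="dark", day=0)
        for j in range(30):
            denom = 0.0
            for s in ("WAKE", "NREM", "REM"):
                m = (hyp.states == s) & (hyp.phase == "light") & (hyp.day_index == 0)
                denom += spec.power[m, j].mean()
            for s in ("WAKE", "NREM", "REM"):
                m = (hyp.states == s) & (hyp.phase == "dark") & (hyp.day_index == 0)
                expected = spec.power[m, j].mean() / denom * 100.0
                assert norm.loc[s].iloc[j] == pytest.approx(expected, rel=1e-10)

    def test_trem_never_contributes_to_state_spectra(self):
        spec, hyp = _random_spec_and_hyp(9)
        # blowing up TREM epochs must not move NREM/REM/WAKE results
        boosted = spec.power.copy()
        boosted[hyp.states == "TREM"] *= 1e6
        a = normalize_cross_state(spec, hyp)
        b = normalize_cross_state(BinnedSpectra(power=boosted), hyp)
        assert np.allclose(a.values, b.values)

    def test_missing_reference_state_reported(self):
        spec, hyp = _random_spec_and_hyp(10)
        hyp.states[(hyp.phase == "light") & (hyp.states == "REM")] = "WAKE"
        with pytest.raises(ValueError, match="REM"):
            normalize_cross_state(spec, hyp)

    def test_within_state_sums_to_100_over_bins(self):
        spec, hyp = _random_spec_and_hyp(11)
        out = normalize_within_state(spec, hyp, "NREM")
        assert out.sum() == pytest.approx(100.0)

    def test_within_state_single_bin_spectrum(self):
        spec, hyp = _random_spec_and_hyp(12)
        power = np.zeros_like(spec.power)
        power[:, 4] = 3.3
        out = normalize_within_state(BinnedSpectra(power=power), hyp, "NREM")
        assert out.iloc[4] == pytest.approx(100.0)
        assert out.drop(out.index[4]).abs().max() == 0

    def test_within_state_matches_direct_formula_oracle(self):
        spec, hyp = _random_spec_and_hyp(13)
        out = normalize_within_state(spec, hyp, "REM", phase="light", day=0)
        m = (hyp.states == "REM") & (hyp.phase == "light") & (hyp.day_index == 0)
        v = spec.power[m].mean(axis=0)
        assert np.allclose(out.to_numpy(), v / v.sum() * 100.0, rtol=1e-10)


class TestBandPower:
    def test_band_confined_spectrum_equals_total(self):
        spec, hyp = _random_spec_and_hyp(14)
        power = np.zeros_like(spec.power)
        delta = BANDS["delta_swa"].bin_mask(spec.bin_labels)
        power[:, delta] = 2.0
        res = band_power(BinnedSpectra(power=power), hyp, BANDS["delta_swa"])
        nrem = hyp.states == "NREM"
        assert np.allclose(res.per_epoch[nrem], 2.0)

    def test_sigma_band_resolves_to_10_through_15(self):
        labels = default_bin_labels()
        assert list(labels[BANDS["sigma"].bin_mask(labels)]) == \
            [10.0, 11.0, 12.0, 13.0, 14.0, 15.0]

    def test_matches_bin_subset_mean_oracle(self):
        spec, hyp = _random_spec_and_hyp(15)
        band = BandDef("custom", 2.0, 8.0)
        res = band_power(spec, hyp, band, state="WAKE")
        sel = (spec.bin_labels >= 2.0) & (spec.bin_labels <= 8.0)
        for i in np.flatnonzero(hyp.states == "WAKE")[:50]:
            assert res.per_epoch.iloc[i] == pytest.approx(
                spec.power[i, sel].mean())

    def test_empty_band_rejected(self):
        spec, hyp = _random_spec_and_hyp(16)
        with pytest.raises(ValueError, match="zero bins"):
            band_power(spec, hyp, BandDef("empty", 25.2, 25.8))


class TestSwaTimecourse:
    def _flat_nrem(self, n_epochs=10800):
        spec = BinnedSpectra(power=np.ones((n_epochs, 30)))
        hyp = Hypnogram.from_states(["NREM"] * n_epochs)
        return spec, hyp

    def test_reference_interval_is_100_percent(self):
        spec, hyp = self._flat_nrem()
        out = swa_timecourse(spec, hyp, interval_h=4.0)
        assert out.loc[8.0] == pytest.approx(100.0)

    def test_reference_window_is_zt8_12_of_day_1(self):
        spec, hyp = self._flat_nrem()
        delta = BANDS["delta_swa"].bin_mask(spec.bin_labels)
        in_ref = (hyp.zt >= 8.0) & (hyp.zt < 12.0)
        spec.power[in_ref][:, delta] *= 1.0  # reference untouched
        spec.power[~in_ref, :] *= 2.0
        out = swa_timecourse(spec, hyp, interval_h=4.0)
        assert out.loc[8.0] == pytest.approx(100.0)
        assert out.loc[0.0] == pytest.approx(200.0)

    def test_piecewise_series_matches_brute_force_means(self):
        rng = np.random.default_rng(17)
        spec, hyp = self._flat_nrem(5400)
        hyp.states[rng.random(5400) < 0.3] = "WAKE"
        spec = BinnedSpectra(power=rng.random((5400, 30)) + 0.1)
        out = swa_timecourse(spec, hyp, interval_h=1.0,
                             ref_zt=(0.0, 2.0))
        delta = BANDS["delta_swa"].bin_mask(spec.bin_labels)
        dvals = spec.power[:, delta].mean(axis=1)
        nrem = hyp.states == "NREM"
        ref = dvals[nrem & (hyp.zt >= 0) & (hyp.zt < 2)].mean()
        for start in out.index:
            m = nrem & (hyp.hours >= start) & (hyp.hours < start + 1.0)
            if m.any():
                assert out.loc[start] == pytest.approx(
                    dvals[m].mean() / ref * 100.0)
            else:
                assert np.isnan(out.loc[start])

    def test_empty_reference_window_rejected(self):
        spec = BinnedSpectra(power=np.ones((900, 30)))
        hyp = Hypnogram.from_states(["WAKE"] * 900)
        with pytest.raises(ValueError, match="ZT8-12|no NREM"):
            swa_timecourse(spec, hyp)
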