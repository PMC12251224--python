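import numpy as np
import pytest
from scipy import signal as sps

from lamstim import (compare_firing, compute_psth, detect_spikes, filter_mua,
                     select_phase_locked_trials)
from lamstim.biophys import PhaseLabels
from lamstim.io import RecordingSession, ValidationError
from lamstim.laminar import LayerMap
from lamstim.mua import robust_noise_sd
from lamstim.synth import _spike_template

FS = 20000.0


def _wb_session(wideband):
    n = wideband.shape[1]
    return RecordingSession(lfp_signals=np.zeros((3, int(n / 10))),
                            fs_lfp=FS / 10, stim_onsets_s=np.array([1.0]),
                            condition="FLASH", wideband_signals=wideband,
                            fs_wideband=FS)


class TestFilterMua:
    def _response(self, freq):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * freq * t)
        out = filter_mua(_wb_session(np.tile(x, (3, 1))))
        return np.abs(out[0, int(FS):-int(FS)]).max()

    def test_mid_band_tone_passes(self):
        assert self._response(1000.0) == pytest.approx(1.0, rel=0.05)

    def test_low_frequency_attenuated(self):
        assert self._response(50.0) < 10 ** (-40 / 20)

    def test_spike_peak_latency_unshifted(self):
        tmpl = _spike_template(FS)
        x = np.zeros(int(2 * FS))
        i0 = 20000
        x[i0:i0 + tmpl.size] = tmpl
        out = filter_mua(_wb_session(np.tile(x, (3, 1))))[0]
        assert abs(int(out.argmax()) - int(x.argmax())) <= 1

    def test_missing_wideband_raises(self):
        sess = RecordingSession(lfp_signals=np.zeros((3, 1000)), fs_lfp=1000.0,
                                stim_onsets_s=np.array([0.5]), condition="FLASH")
        with pytest.raises(ValidationError):
            filter_mua(sess)


class TestDetectSpikes:
    def test_threshold_is_3p5_sd_on_unit_gaussian(self, rng):
        x = rng.standard_normal(10 ** 6)
        st = detect_spikes(x[None, :], FS, alpha=3.5)
        assert st.thresholds[0] == pytest.approx(3.5, abs=0.01)

    def test_noise_sd_estimator_is_consistent(self, rng):
        x = 2.7 * rng.standard_normal(10 ** 6)
        assert robust_noise_sd(x) == pytest.approx(2.7, rel=0.01)

    def test_injected_events_recovered_within_half_ms(self, rng):
        # band-limited noise so the Rice crossing rate is moderate
        sos = sps.butter(4, (300, 5000), btype="bandpass", fs=FS, output="sos")
        noise = sps.sosfiltfilt(sos, rng.standard_normal(int(20 * FS)))
        noise /= noise.std()
        tmpl = _spike_template(FS)
        injected = np.array([2.0, 7.5, 15.0])
        for t0 in injected:
            i = int(t0 * FS)
            noise[i:i + tmpl.size] += 10.0 * tmpl
        st = detect_spikes(noise[None, :], FS, 3.5)
        for t0 in injected:
            assert np.min(np.abs(st.spike_times_s[0] - t0)) < 0.5e-3

    def test_false_rate_matches_rice_expectation_within_factor_two(self, rng):
        sos = sps.butter(4, (300, 5000), btype="bandpass", fs=FS, output="sos")
        noise = sps.sosfiltfilt(sos, rng.standard_normal(int(30 * FS)))
        sigma = noise.std()
        st = detect_spikes(noise[None, :], FS, 3.5)
        observed = st.spike_times_s[0].size / 30.0
        # Rice upcrossing rate of level u for a Gaussian process
        f_eff = np.sqrt((np.gradient(noise) * FS).var() / noise.var()) / (2 * np.pi)
        expected = f_eff * np.exp(-0.5 * (3.5 * robust_noise_sd(noise) / sigma) ** 2)
        assert expected / 2 <= observed <= expected * 2

    def test_all_zero_signal_yields_no_events(self):
        st = detect_spikes(np.zeros((2, int(2 * FS))), FS, 3.5)
        assert st.thresholds.tolist() == [0.0, 0.0]
        assert all(s.size == 0 for s in st.spike_times_s)

    def test_dead_time_merges_adjacent_crossings(self):
        x = np.zeros(int(2 * FS))
        x[1000] = x[1005] = x[1015] = 10.0   # all within 1 ms of the first
        noise = 0.1 * np.sin(2 * np.pi * 1000 * np.arange(x.size) / FS)
        st = detect_spikes((x + noise)[None, :], FS, 3.5)
        assert st.spike_times_s[0].size == 1

    def test_invalid_alpha_raises(self):
        with pytest.raises(ValidationError):
            detect_spikes(np.zeros((1, int(2 * FS))), FS, alpha=0.0)


class TestPsth:
    def test_single_locked_spike_fills_first_bin(self):
        onsets = np.arange(100) * 0.435 + 1.0
        spikes = _manual_spikes([onsets + 0.005])
        lmap = LayerMap(labels=("L56",), provenance="manual")
        psth = compute_psth(spikes, onsets, lmap)
        assert psth.rates[0, 0] == pytest.approx(100.0)
        assert np.all(psth.rates[0, 1:] == 0.0)

    def test_no_spikes_gives_zero_psth(self):
        lmap = LayerMap(labels=("L4C",), provenance="manual")
        psth = compute_psth(_manual_spikes([np.array([])]), np.array([1.0]), lmap)
        np.testing.assert_array_equal(psth.rates, 0.0)

    def test_homogeneous_poisson_rate_recovered(self, rng):
        rate = 20.0
        events = np.sort(rng.uniform(0, 300.0, rng.poisson(rate * 300)))
        onsets = np.arange(1.0, 290.0, 1.45)
        lmap = LayerMap(labels=("L23",), provenance="manual")
        psth = compute_psth(_manual_spikes([events]), onsets, lmap)
        assert psth.trial_rates.mean() == pytest.approx(rate, abs=1.0)

    def test_bin_must_divide_window(self):
        lmap = LayerMap(labels=("L23",), provenance="manual")
        with pytest.raises(ValidationError):
            compute_psth(_manual_spikes([np.array([1.0])]), np.array([1.0]),
                         lmap, bin_ms=7.0)


def _manual_spikes(times_per_contact):
    from lamstim.mua import SpikeTrainSet
    return SpikeTrainSet(spike_times_s=tuple(np.asarray(t) for t in times_per_contact),
                         thresholds=np.ones(len(times_per_contact)),
                         alpha=3.5, band_hz=(300.0, 5000.0), fs=FS)


class TestPhaseLockedSelection:
    def _labels(self, phases):
        return PhaseLabels(phase_deg=np.asarray(phases, float),
                           valid=np.ones(len(phases), bool), method="virtual")

    def test_peak_and_trough_windows(self):
        labels = self._labels([0.0, 90.0, 179.0])
        assert select_phase_locked_trials(labels, "peak").tolist() == [0]
        assert select_phase_locked_trials(labels, "trough").tolist() == [2]

    def test_uniform_labels_capture_about_a_quarter(self, rng):
        labels = self._labels(rng.uniform(-180, 180, 4000))
        frac = select_phase_locked_trials(labels, "peak").size / 4000
        assert 0.20 <= frac <= 0.30

    def test_window_bounds_validated(self):
        with pytest.raises(ValidationError):
            select_phase_locked_trials(self._labels([0.0]), "peak", window_deg=100.0)


class TestCompareFiring:
    def test_identical_paired_samples(self):
        t, p = compare_firing(np.ones(10), np.ones(10), "paired")
        assert t == 0.0 and p == 1.0

    def test_separated_means_unpaired(self, rng):
        a = 5.0 + rng.standard_normal(100)
        b = 10.0 + rng.standard_normal(100)
        t, p = compare_firing(a, b, "unpaired")
        assert p < 1e-6 and t < 0

    def test_paired_with_unequal_lengths_raises(self):
        with pytest.raises(ValidationError):
            compare_firing(np.ones(5), np.ones(6), "paired")

    def test_single_observation_raises(self):
        with pytest.raises(ValidationError):
            compare_firing(np.ones(1), np.ones(5), "unpaired")
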