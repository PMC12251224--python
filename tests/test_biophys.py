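import numpy as np
import pytest

from lamstim import (RecordingSession, compute_efield, extract_ac_waveform,
                     extract_amp_phase, phase_at_onsets, rayleigh_test,
                     virtual_ac_labels)
from lamstim.io import ValidationError
from lamstim.synth import wrap_deg


def _ac_session(signals, fs=2000.0, condition="FLASH_AC", onsets=(10.0,)):
    return RecordingSession(lfp_signals=signals, fs_lfp=fs,
                            stim_onsets_s=np.array(onsets), condition=condition)


class TestExtractAcWaveform:
    def test_gain_division_recovers_physical_mV(self):
        fs = 2000.0
        t = np.arange(int(30 * fs)) / fs
        sig = 10.0 * np.cos(2 * np.pi * 1.5 * t)
        out = extract_ac_waveform(_ac_session(np.tile(sig, (3, 1))))
        mid = out[0, 5000:-5000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.02)

    def test_line_noise_attenuated(self):
        fs = 2000.0
        t = np.arange(int(30 * fs)) / fs
        sig = np.cos(2 * np.pi * 60.0 * t)
        out = extract_ac_waveform(_ac_session(np.tile(sig, (3, 1))))
        att = np.abs(out[0, 5000:-5000]).max() * 10.0  # undo gain division
        assert att < 10 ** (-40 / 20)

    def test_white_noise_output_is_band_limited(self):
        rng = np.random.default_rng(0)
        fs = 2000.0
        out = extract_ac_waveform(_ac_session(rng.standard_normal((3, int(30 * fs)))))
        spec = np.abs(np.fft.rfft(out[0])) ** 2
        freqs = np.fft.rfftfreq(out.shape[1], d=1e-3)
        assert spec[freqs > 3.0].sum() < 0.01 * spec.sum()

    def test_short_record_raises(self):
        with pytest.raises(ValidationError, match="cycles"):
            extract_ac_waveform(_ac_session(np.zeros((3, 4000)), onsets=(1.0,)))


class TestComputeEfield:
    def test_linear_profile_gives_constant_field(self):
        field = compute_efield(np.array([0.0, 1.0, 2.0, 3.0]), 0.1)
        np.testing.assert_allclose(field, 10.0)

    def test_constant_profile_gives_zero_field(self):
        np.testing.assert_allclose(compute_efield(np.full(5, 2.5), 0.1), 0.0)

    def test_quadratic_profile_matches_analytic_interior_derivative(self):
        i = np.arange(5.0)
        spacing = 0.1
        field = compute_efield(i ** 2, spacing)
        # d/dx of (x/spacing)^2 * spacing^2 evaluated at contacts: 2*i*spacing
        np.testing.assert_allclose(field[1:-1], 2.0 * i[1:-1] / spacing)

    @pytest.mark.parametrize("profile,spacing", [
        (np.array([1.0, 2.0]), 0.1), (np.arange(5.0), 0.0)])
    def test_invalid_inputs_raise(self, profile, spacing):
        with pytest.raises(ValidationError):
            compute_efield(profile, spacing)


class TestExtractAmpPhase:
    def test_cosine_amplitude_phase_frequency(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        amp, ph, f = extract_amp_phase(2.0 * np.cos(2 * np.pi * 1.5 * t), fs)
        assert amp == pytest.approx(2.0, rel=1e-3)
        assert ph == pytest.approx(0.0, abs=0.5)
        assert f == pytest.approx(1.5, abs=0.01)

    def test_phase_lag_reported_in_cosine_convention(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        x = 2.0 * np.cos(2 * np.pi * 1.5 * t - np.pi / 2)
        _, ph, _ = extract_amp_phase(x, fs)
        assert ph == pytest.approx(-90.0, abs=0.5)

    def test_dominant_bin_selected_in_two_tone_signal(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        x = 3.0 * np.cos(2 * np.pi * 1.5 * t) + 1.0 * np.cos(2 * np.pi * 5.0 * t)
        amp, _, f = extract_amp_phase(x, fs)
        assert f == pytest.approx(1.5, abs=0.01)
        assert amp == pytest.approx(3.0, rel=0.01)

    def test_all_zero_signal_raises(self):
        with pytest.raises(ValidationError):
            extract_amp_phase(np.zeros(8000), 1000.0)


class TestPhaseAtOnsets:
    def test_cosine_peak_onset_is_zero_degrees(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        x = np.cos(2 * np.pi * 1.5 * t)
        labels = phase_at_onsets(x, fs, np.array([10.0 / 1.5]))  # on a peak
        assert labels.phase_deg[0] == pytest.approx(0.0, abs=1.0)

    def test_quarter_period_after_peak_is_plus_90(self):
        fs = 1000.0
        T = 1 / 1.5
        t = np.arange(int(20 * fs)) / fs
        x = np.cos(2 * np.pi * 1.5 * t)
        labels = phase_at_onsets(x, fs, np.array([10 * T + T / 4]))
        assert labels.phase_deg[0] == pytest.approx(90.0, abs=1.0)

    def test_edge_onsets_marked_invalid(self):
        fs = 1000.0
        x = np.cos(2 * np.pi * 1.5 * np.arange(int(10 * fs)) / fs)
        labels = phase_at_onsets(x, fs, np.array([0.1, 5.0, 9.9]))
        assert labels.valid.tolist() == [False, True, False]

    def test_incommensurate_onset_train_is_uniform(self):
        fs = 1000.0
        t = np.arange(int(120 * fs)) / fs
        x = np.cos(2 * np.pi * 1.5 * t)
        onsets = np.arange(2.0, 110.0, 1 / 2.3)[:200]
        labels = phase_at_onsets(x, fs, onsets)
        assert rayleigh_test(labels) > 0.05

    def test_hilbert_agrees_with_fft_phase_on_stationary_tone(self):
        fs = 1000.0
        t = np.arange(int(40 * fs)) / fs
        x = np.cos(2 * np.pi * 1.5 * t - 1.0)
        onset = np.array([20.0])
        lab = phase_at_onsets(x, fs, onset)
        _, ph_fft, _ = extract_amp_phase(x, fs)
        expected = wrap_deg(ph_fft + 360.0 * 1.5 * onset[0])
        d = wrap_deg(lab.phase_deg[0] - expected)
        assert abs(d) < 5.0


class TestVirtualLabels:
    def _flash(self, onsets):
        return RecordingSession(lfp_signals=np.zeros((3, 200000)), fs_lfp=2000.0,
                                stim_onsets_s=np.asarray(onsets),
                                condition="FLASH")

    def test_onsets_at_period_multiples_are_zero(self):
        labels = virtual_ac_labels(self._flash(np.arange(1, 50) / 1.5), f0=1.5)
        np.testing.assert_allclose(wrap_deg(labels.phase_deg), 0.0, atol=1e-6)

    def test_matches_closed_form_sequence(self):
        f0, f_flash = 1.5, 2.3
        onsets = 10.0 + np.arange(100) / f_flash
        labels = virtual_ac_labels(self._flash(onsets), f0=f0)
        k = np.arange(100)
        expected = wrap_deg(360.0 * f0 * 10.0 + 360.0 * f0 * k / f_flash)
        np.testing.assert_allclose(wrap_deg(labels.phase_deg - expected), 0.0,
                                   atol=1e-6)

    def test_stimulation_condition_rejected(self, small_pair):
        _, flash_ac, _ = small_pair
        with pytest.raises(ValidationError):
            virtual_ac_labels(flash_ac)


def test_labels_recover_generator_truth(small_pair):
    """Hilbert phase labels on the synthetic stimulation record match the
    generator's injected onset phases within 5 degrees for >= 99% of trials."""
    _, flash_ac, truth = small_pair
    ac = extract_ac_waveform(flash_ac)
    ref = int(np.argmax(np.abs(ac).max(axis=1)))
    labels = phase_at_onsets(ac[ref], 1000.0, flash_ac.stim_onsets_s)
    err = np.abs(wrap_deg(labels.phase_deg - truth.phases_deg))
    assert np.mean(err <= 5.0) >= 0.99
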