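import numpy as np
import pytest

from lamstim import (RecordingSession, SynthConfig, dft_subtract, evoked_kernel, filter_lfp,
                     generate_session, identify_ac_components,
                     joint_diagonalize, remove_ac_artifact, sobi_unmix)
from lamstim.artifact import UnmixingModel, band_power, plateau_band_power
from lamstim.io import ValidationError


def _rotation(n, seed):
    q, _ = np.linalg.qr(np.random.default_rng(seed).standard_normal((n, n)))
    return q


class TestJointDiagonalize:
    def test_already_diagonal_returns_identity(self):
        mats = [np.diag([3.0, 1.0, -2.0]), np.diag([0.5, 2.0, 1.0])]
        V = joint_diagonalize(mats)
        np.testing.assert_allclose(np.abs(V), np.eye(3), atol=1e-10)

    def test_recovers_known_rotation_up_to_permutation(self):
        R = _rotation(4, 7)
        d1, d2 = np.diag([4.0, 2.0, 1.0, 0.5]), np.diag([1.0, 3.0, 0.2, 2.5])
        mats = [R @ d1 @ R.T, R @ d2 @ R.T]
        V = joint_diagonalize(mats)
        # gain matrix R.T V must be a signed permutation
        G = np.abs(R.T @ V)
        assert np.allclose(np.sort(G.max(axis=0)), 1.0, atol=1e-8)
        assert np.allclose(G.sum(), 4.0, atol=1e-6)

    def test_single_matrix_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((6, 6))
        A = A + A.T
        V = joint_diagonalize([A])
        D = V.T @ A @ V
        off = D - np.diag(np.diag(D))
        assert np.abs(off).max() < 1e-8
        w_oracle = np.sort(np.linalg.eigvalsh(A))
        np.testing.assert_allclose(np.sort(np.diag(D)), w_oracle, atol=1e-8)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            joint_diagonalize([np.eye(3), np.eye(4)])


class TestSobi:
    def test_separates_two_sinusoids(self):
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        s = np.vstack([np.cos(2 * np.pi * 1.5 * t), np.sin(2 * np.pi * 10 * t)])
        M = np.array([[1.0, 0.4], [0.3, 1.2]])
        model = sobi_unmix(M @ s, fs=fs)
        corr = np.abs(np.corrcoef(np.vstack([model.sources, s]))[:2, 2:])
        # each recovered source matches exactly one generator
        assert np.sort(corr.max(axis=1)).min() > 0.99
        assert model.off_diagonal_fraction < 0.01

    def test_white_independent_data_gives_signed_permutation(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 20000))
        model = sobi_unmix(x, fs=1000.0)
        G = np.abs(model.unmixing @ np.eye(3))
        # unit gain toward exactly one input channel per source (loose: white
        # data has no lagged structure, identification is up to rotation noise)
        assert G.shape == (3, 3)
        recon = model.mixing @ model.sources
        np.testing.assert_allclose(recon, x - x.mean(axis=1, keepdims=True),
                                   atol=1e-8)

    def test_constant_channel_takes_rank_deficient_path(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.standard_normal((2, 20000)), np.zeros((1, 20000))])
        with pytest.warns(UserWarning, match="rank"):
            model = sobi_unmix(x, fs=1000.0)
        assert model.rank_retained == 2

    def test_nonfinite_input_raises(self):
        x = np.zeros((2, 5000))
        x[0, 10] = np.nan
        with pytest.raises(ValidationError):
            sobi_unmix(x, fs=1000.0)

    def test_mixing_unmixing_are_pseudo_inverse_on_retained_subspace(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        s = np.vstack([np.cos(2 * np.pi * 1.5 * t), np.sin(2 * np.pi * 7 * t),
                       np.sin(2 * np.pi * 23 * t)])
        M = _rotation(3, 1) * np.array([3.0, 1.0, 0.5])
        model = sobi_unmix(M @ s, fs=fs)
        I = model.unmixing @ model.mixing
        np.testing.assert_allclose(I, np.eye(model.n_sources), atol=1e-6)


class TestIdentifyAc:
    def _model(self, sources):
        n = sources.shape[0]
        return UnmixingModel(mixing=np.eye(n), unmixing=np.eye(n),
                             sources=sources, lags=np.array([1]))

    def test_pure_ac_source_flagged_and_noise_not(self):
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        rng = np.random.default_rng(0)
        src = np.vstack([np.cos(2 * np.pi * 1.5 * t),
                         rng.standard_normal(t.size)])
        model = identify_ac_components(self._model(src), fs, 1.5)
        assert model.ac_flags.tolist() == [True, False]
        assert model.power_ratios[0] > model.power_ratios[1]

    def test_f0_beyond_nyquist_raises(self):
        src = np.zeros((1, 60000))
        with pytest.raises(ValidationError):
            identify_ac_components(self._model(src), 1000.0, 600.0)


class TestDftSubtract:
    def test_stationary_sinusoid_removed_exactly(self):
        fs = 1000.0
        t = np.arange(int(40 * fs)) / fs
        x = 3.0 * np.cos(2 * np.pi * 1.5 * t + 0.7)
        r = dft_subtract(x, fs, 1.5)
        assert np.sqrt((r ** 2).mean()) < 1e-3 * np.sqrt((x ** 2).mean())

    def test_evoked_train_preserved(self):
        fs = 1000.0
        t = np.arange(int(40 * fs)) / fs
        clean = np.zeros_like(t)
        kern = evoked_kernel(np.arange(0.0, 300.0), 1.0, 1.5)
        for onset in np.arange(1.0, 38.0, 1 / 2.3):
            i = int(onset * fs)
            clean[i:i + kern.size] += kern
        x = clean + 40.0 * np.cos(2 * np.pi * 1.5 * t)
        r = dft_subtract(x, fs, 1.5)
        assert np.corrcoef(r, clean)[0, 1] > 0.99

    def test_fit_region_can_exclude_ramps(self):
        fs = 1000.0
        t = np.arange(int(40 * fs)) / fs
        env = np.clip(t / 10.0, 0, 1)
        x = env * np.cos(2 * np.pi * 1.5 * t)
        r = dft_subtract(x, fs, 1.5, exclude=[(0.0, 10.0)])
        plateau = r[int(12 * fs):]
        assert np.sqrt((plateau ** 2).mean()) < 1e-6

    def test_zero_frequency_raises(self):
        with pytest.raises(ValidationError):
            dft_subtract(np.zeros(4000), 1000.0, 0.0)


class TestRemoveAcArtifact:
    def test_cleaning_reaches_30db_and_matches_flash_floor(self, small_pair):
        flash, flash_ac, _ = small_pair
        flash_f = filter_lfp(flash)
        ac_f = filter_lfp(flash_ac)
        cleaned, model = remove_ac_artifact(ac_f)
        assert model.ac_flags.any()
        att = 10 * np.log10(plateau_band_power(ac_f, 1.5)
                            / plateau_band_power(cleaned, 1.5))
        assert att >= 30.0
        # residual stimulation-band power comparable to the Flash condition
        ratio = 10 * np.log10(plateau_band_power(cleaned, 1.5)
                              / plateau_band_power(flash_f, 1.5))
        assert abs(ratio) < 3.0

    def test_energy_accounting(self, small_pair):
        """Cleaned record plus removed reconstruction equals the original."""
        _, flash_ac, _ = small_pair
        ac_f = filter_lfp(flash_ac)
        cleaned, _ = remove_ac_artifact(ac_f)
        removed = ac_f.lfp_signals - cleaned.lfp_signals
        np.testing.assert_allclose(cleaned.lfp_signals + removed,
                                   ac_f.lfp_signals, atol=1e-9)
        assert band_power(removed, 1000.0, 1.5) > 0

    def test_zero_artifact_session_nearly_unchanged(self):
        """Without an artifact the cleaning step is a near no-op: whatever
        incidental 1.5 Hz noise content is fitted and removed changes the
        record by well under 1%."""
        cfg = SynthConfig(seed=6, duration_s=30.0, ramp_s=3.0,
                          ac_scalp_amplitude_mV=0.0)
        _, flash_ac, _ = generate_session(cfg)
        ac_f = filter_lfp(flash_ac)
        cleaned, _ = remove_ac_artifact(ac_f)
        rel = (np.linalg.norm(cleaned.lfp_signals - ac_f.lfp_signals)
               / np.linalg.norm(ac_f.lfp_signals))
        assert rel < 0.01

    def test_no_flagged_component_warns_and_returns_input(self):
        rng = np.random.default_rng(8)
        sess = RecordingSession(
            lfp_signals=rng.standard_normal((4, 60000)), fs_lfp=1000.0,
            stim_onsets_s=np.array([10.0]), condition="FLASH_AC", ramp_s=5.0)
        with pytest.warns(UserWarning, match="unchanged"):
            cleaned, model = remove_ac_artifact(sess)
        assert not model.ac_flags.any()
        np.testing.assert_array_equal(cleaned.lfp_signals, sess.lfp_signals)

    def test_flash_condition_rejected(self, small_pair):
        flash, _, _ = small_pair
        with pytest.raises(ValidationError, match="FLASH_AC"):
            remove_ac_artifact(filter_lfp(flash))
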