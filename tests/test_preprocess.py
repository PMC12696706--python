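import numpy as np
import pytest

from conftest import tone_recording
from docbci.core import (
    SCALP_CHANNELS,
    ConfigurationError,
    EEGRecording,
    ProcessingError,
    SessionPlan,
)
from docbci.preprocess import (
    PreprocessConfig,
    attenuate_artifacts_ica,
    bandpass_and_notch,
    compute_snr,
    decompose_bands,
    detect_bad_channels,
    epoch_and_reject,
    interpolate_bad_channels,
    preprocess_recording,
    rereference_car,
)
from docbci.spectral import welch_psd_array
from docbci.synthetic_eeg import make_cohort, synthesize_recording


def noise_recording(fs=500.0, seconds=20.0, n_channels=30, seed=0,
                    scale=10.0):
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, scale, size=(n_channels, int(seconds * fs)))
    return EEGRecording(data=data, fs=fs,
                        channel_names=list(SCALP_CHANNELS[:n_channels]),
                        condition="rest")


class TestBandpassAndNotch:
    def test_line_noise_suppressed(self):
        rec = tone_recording(50.0, fs=500.0)
        out = bandpass_and_notch(rec)
        assert np.sqrt(np.mean(out.data**2)) < 0.1 * np.sqrt(
            np.mean(rec.data**2))

    def test_passband_preserved(self):
        rec = tone_recording(10.0, fs=500.0)
        out = bandpass_and_notch(rec)
        mid = out.data[:, 1000:-1000]  # away from edges
        assert np.max(np.abs(mid)) == pytest.approx(10.0, rel=0.05)

    def test_out_of_band_attenuated_on_white_noise(self):
        rec = noise_recording(seconds=60.0)
        out = bandpass_and_notch(rec)
        freqs, psd = welch_psd_array(out.data, out.fs, window_s=8.0)
        p = psd.mean(axis=0)

        def at(f):
            return p[np.argmin(np.abs(freqs - f))]

        assert at(0.25) < 0.01 * at(10.0)
        assert at(80.0) < 0.01 * at(10.0)
        assert at(50.0) < 0.01 * at(10.0)

    def test_fs_too_low_rejected(self):
        rec = tone_recording(10.0, fs=90.0)
        with pytest.raises(ConfigurationError):
            bandpass_and_notch(rec)

    def test_zero_phase_preserves_event_alignment(self):
        # an impulse-like bump stays centered after filtering
        rec = noise_recording(seconds=10.0, n_channels=2, scale=0.1)
        data = rec.data.copy()
        data[0, 2500:2520] += 50.0
        out = bandpass_and_notch(rec.with_data(data))
        assert abs(int(np.argmax(np.abs(out.data[0]))) - 2510) < 30


class TestDecomposeBands:
    def test_single_band_input_stays_in_band(self):
        rec = bandpass_and_notch(tone_recording(2.0, fs=500.0, seconds=20))
        subs = decompose_bands(rec)
        p_total = sum(np.mean(s.data**2) for s in subs.values())
        for name in ("theta", "alpha", "beta", "gamma"):
            assert np.mean(subs[name].data**2) < 0.05 * p_total

    def test_alpha_tone_lands_only_in_alpha(self):
        rec = bandpass_and_notch(tone_recording(11.0, fs=500.0, seconds=20))
        subs = decompose_bands(rec)
        p_alpha = np.mean(subs["alpha"].data**2)
        for name in ("delta", "theta", "beta", "gamma"):
            assert np.mean(subs[name].data**2) < 0.01 * p_alpha

    def test_contiguous_bands_reconstruct_broadband_energy(
            self, mcs_profile):
        # EEG-weighted noise: the 6th-order band edges overlap at half
        # power, so the tiling loses a little energy at each boundary
        plan = SessionPlan(rest_duration_s=30.0)
        rec = synthesize_recording(mcs_profile, plan, "rest", seed=4,
                                   artifact_rate=0, blink_rate=0)
        filt = bandpass_and_notch(rec)
        subs = decompose_bands(filt)
        e_broad = np.sum(filt.data[filt.scalp_indices]**2)
        e_sum = sum(np.sum(s.data[s.scalp_indices]**2)
                    for s in subs.values())
        assert e_sum == pytest.approx(e_broad, rel=0.10)


class TestBadChannels:
    def test_no_bad_channels_is_identity(self):
        rec = noise_recording(seconds=10.0)
        out = interpolate_bad_channels(rec, bad=[])
        assert np.array_equal(out.data, rec.data)

    def test_dead_channel_flagged_and_replaced(self, mcs_profile):
        plan = SessionPlan(rest_duration_s=30.0)
        rec = synthesize_recording(mcs_profile, plan, "rest", seed=1,
                                   artifact_rate=0, blink_rate=0)
        data = rec.data.copy()
        data[rec.channel_index("P3")] = 0.0
        broken = rec.with_data(data)
        assert detect_bad_channels(broken) == ["P3"]
        fixed = interpolate_bad_channels(broken)
        rms = np.sqrt(np.mean(fixed.data[fixed.scalp_indices]**2, axis=-1))
        med = np.median(rms)
        p3 = np.sqrt(np.mean(fixed.data[fixed.channel_index("P3")]**2))
        assert 0 < p3 < 3 * med
        untouched = [i for i in rec.scalp_indices
                     if rec.channel_names[i] != "P3"]
        assert np.array_equal(fixed.data[untouched], broken.data[untouched])

    def test_adjacent_bad_channels_use_good_neighbors_only(self,
                                                           mcs_profile):
        plan = SessionPlan(rest_duration_s=20.0)
        rec = synthesize_recording(mcs_profile, plan, "rest", seed=2,
                                   artifact_rate=0, blink_rate=0)
        a = rec.data.copy()
        a[rec.channel_index("Fp1")] = 0.0
        a[rec.channel_index("Fp2")] = 0.0
        fixed_a = interpolate_bad_channels(rec.with_data(a),
                                           bad=["Fp1", "Fp2"])
        b = rec.data.copy()
        b[rec.channel_index("Fp1")] = 0.0
        b[rec.channel_index("Fp2")] = 1000.0  # different garbage
        fixed_b = interpolate_bad_channels(rec.with_data(b),
                                           bad=["Fp1", "Fp2"])
        # Fp1's interpolation is unchanged by what the other bad channel
        # contained, i.e. the weights exclude the bad set entirely
        i = rec.channel_index("Fp1")
        assert np.array_equal(fixed_a.data[i], fixed_b.data[i])
        assert np.std(fixed_a.data[i]) > 0

    def test_too_many_bad_channels_flags_subject(self):
        rec = noise_recording(seconds=5.0)
        with pytest.raises(ProcessingError):
            interpolate_bad_channels(rec, bad=list(SCALP_CHANNELS[:10]))


@pytest.fixture(scope="module")
def blinky(mcs_profile):
    plan = SessionPlan(rest_duration_s=60.0, fs_rest=250.0)
    rec = synthesize_recording(mcs_profile, plan, "rest", seed=4,
                               artifact_rate=0, blink_rate=12)
    return bandpass_and_notch(rec)


class TestICA:
    def test_single_ocular_source_removed(self, blinky, mcs_profile):
        clean, n_removed = attenuate_artifacts_ica(blinky, seed=0)
        assert n_removed == 1
        # frontal delta-range artifact power reduced >= 70%
        from scipy import signal as sp

        plan = SessionPlan(rest_duration_s=60.0, fs_rest=250.0)
        raw = synthesize_recording(mcs_profile, plan, "rest", seed=4,
                                   artifact_rate=0, blink_rate=12)
        art = raw.truth["artifact_signal"]
        fp1 = raw.truth["scalp_names"].index("Fp1")
        sos = sp.butter(3, [1, 4], btype="bandpass", fs=raw.fs, output="sos")
        i_fp1 = blinky.channel_index("Fp1")
        p_before = np.mean(sp.sosfiltfilt(sos, blinky.data[i_fp1])**2)
        p_after = np.mean(sp.sosfiltfilt(sos, clean.data[i_fp1])**2)
        p_art = np.mean(sp.sosfiltfilt(sos, art[fp1])**2)
        assert (p_before - p_after) / p_art >= 0.70

    def test_deterministic_given_seed(self, blinky):
        a, na = attenuate_artifacts_ica(blinky, seed=0)
        b, nb = attenuate_artifacts_ica(blinky, seed=0)
        assert na == nb
        assert np.array_equal(a.data, b.data)

    def test_artifact_free_data_untouched(self, mcs_profile):
        plan = SessionPlan(rest_duration_s=60.0, fs_rest=250.0)
        rec = synthesize_recording(mcs_profile, plan, "rest", seed=5,
                                   artifact_rate=0, blink_rate=0)
        filt = bandpass_and_notch(rec)
        clean, n_removed = attenuate_artifacts_ica(filt, seed=0)
        assert n_removed == 0
        for i in filt.scalp_indices:
            assert np.corrcoef(clean.data[i], filt.data[i])[0, 1] > 0.99

    def test_short_data_rejected(self):
        rec = noise_recording(seconds=10.0)
        with pytest.raises(ConfigurationError):
            attenuate_artifacts_ica(rec)


class TestCAR:
    def test_scalp_mean_is_zero_everywhere(self):
        rec = noise_recording(seconds=5.0)
        out = rereference_car(rec)
        assert np.max(np.abs(out.data[out.scalp_indices].mean(axis=0))) \
            < 1e-9

    def test_idempotent(self):
        rec = noise_recording(seconds=5.0)
        once = rereference_car(rec)
        twice = rereference_car(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_offset_redistributed(self):
        rec = noise_recording(seconds=2.0)
        base = rereference_car(rec)
        data = rec.data.copy()
        data[3] += 10.0
        shifted = rereference_car(rec.with_data(data))
        delta = shifted.data - base.data
        assert np.allclose(delta[3], 10.0 * 29 / 30, atol=1e-9)
        others = [i for i in range(30) if i != 3]
        assert np.allclose(delta[others], -10.0 / 30, atol=1e-9)


class TestEpochAndReject:
    def test_three_hundred_seconds_gives_sixty_epochs(self):
        rec = noise_recording(fs=250.0, seconds=300.0, n_channels=3,
                              scale=5.0)
        epochs = epoch_and_reject(rec)
        assert epochs.n_epochs == 60

    def test_single_spike_rejects_exactly_its_epoch(self):
        rec = noise_recording(fs=250.0, seconds=30.0, n_channels=3,
                              scale=5.0)
        data = rec.data.copy()
        data[1, int(12.0 * rec.fs)] = 100.0
        epochs = epoch_and_reject(rec.with_data(data))
        assert list(np.nonzero(~epochs.keep)[0]) == [2]  # covers 10-15 s

    def test_boundary_amplitude_kept(self):
        rec = noise_recording(fs=250.0, seconds=20.0, n_channels=3,
                              scale=5.0)
        data = rec.data / np.max(np.abs(rec.data)) * 74.9
        epochs = epoch_and_reject(rec.with_data(data))
        assert epochs.n_kept == epochs.n_epochs

    def test_rejection_is_idempotent(self, mcs_profile):
        plan = SessionPlan(rest_duration_s=60.0)
        rec = synthesize_recording(mcs_profile, plan, "rest", seed=6,
                                   artifact_rate=4, blink_rate=8)
        epochs = epoch_and_reject(rec)
        kept = epochs.kept_data  # (n, ch, samp)
        flat = kept.transpose(1, 0, 2).reshape(kept.shape[1], -1)
        again = epoch_and_reject(rec.with_data(flat))
        assert again.n_kept == again.n_epochs


class TestSNR:
    def _rec_with_trials(self, scale_task=1.0, fs=250.0, n_trials=5):
        rng = np.random.default_rng(3)
        plan = SessionPlan(n_trials=n_trials, n_practice=0)
        n = int(plan.task_duration_s * fs)
        data = rng.normal(0.0, 10.0, size=(4, n))
        events = []
        for start in plan.trial_starts_s():
            on = int((start + plan.trial_baseline_s) * fs)
            off = int((start + plan.trial_baseline_s + plan.trial_cue_s)
                      * fs)
            data[:, on:off] *= scale_task
            events.append((on, "cue_on"))
            events.append((off, "cue_off"))
        return EEGRecording(data=data, fs=fs,
                            channel_names=list(SCALP_CHANNELS[:4]),
                            condition="task", events=events)

    def test_identical_windows_give_zero_db(self):
        rep = compute_snr(self._rec_with_trials(1.0))
        assert abs(rep.snr_db) < 0.5

    def test_doubled_task_power_gives_three_db(self):
        rep = compute_snr(self._rec_with_trials(np.sqrt(2.0)))
        assert rep.snr_db == pytest.approx(10 * np.log10(2), abs=0.5)

    def test_missing_events_rejected(self):
        rec = self._rec_with_trials(1.0)
        rec.events.clear()
        with pytest.raises(ConfigurationError):
            compute_snr(rec)

    def test_cleaning_improves_mean_snr(self):
        """Artifact-laden sessions: post-cleaning SNR exceeds
        pre-cleaning SNR on average (amplitude screen + ICA remove the
        baseline-concentrated movement/ocular contamination)."""
        plan = SessionPlan(n_trials=12, n_practice=0, rest_duration_s=10.0)
        cohort = make_cohort(2, 2, seed=5)
        pre, post = [], []
        for i, p in enumerate(cohort):
            task = synthesize_recording(p, plan, "task", artifact_rate=10,
                                        blink_rate=10, seed=70 + i)
            pre.append(compute_snr(task).snr_db)
            clean, _, _ = preprocess_recording(task, PreprocessConfig())
            post.append(compute_snr(clean, reject_uv=75.0).snr_db)
        assert np.mean(post) > np.mean(pre)


class TestFullChain:
    def test_order_and_qc(self, mcs_profile):
        plan = SessionPlan(n_trials=3, n_practice=0, rest_duration_s=30.0)
        rec = synthesize_recording(mcs_profile, plan, "task", seed=9,
                                   artifact_rate=2, blink_rate=6)
        clean, epochs, qc = preprocess_recording(
            rec, PreprocessConfig(run_ica=False))
        assert qc["order"] == ["filter", "bad_channels", "ica", "car",
                               "epoch"]
        assert qc["n_epochs"] == epochs.n_epochs
        assert qc["n_kept"] + qc["n_rejected"] == qc["n_epochs"]
        # CAR property holds on the cleaned output
        assert np.max(np.abs(
            clean.data[clean.scalp_indices].mean(axis=0))) < 1e-9
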