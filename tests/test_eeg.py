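"""EEG pipeline: sync detection, preprocessing, artifact masking, features."""

import numpy as np
import pandas as pd
import pytest

from affectpipe import eeg
from affectpipe import synthetic as syn

FS = 128.0


def _sine(freq, amp, dur=30.0, fs=FS, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


def _recording(signals: dict[str, np.ndarray], sync=None) -> eeg.EEGRecording:
    chans = list(signals)
    return eeg.EEGRecording(
        data=np.vstack([signals[c] for c in chans]), channels=chans, sfreq=FS, sync=sync
    )


class TestSyncDetection:
    def test_single_clean_pulse(self):
        sync = np.zeros(4000)
        sync[1280:1408] = 200.0
        assert eeg.detect_sync_events(sync, FS) == [1280]

    def test_all_zero_returns_empty(self):
        assert eeg.detect_sync_events(np.zeros(1000), FS) == []

    def test_round_trip_with_simulated_timeline(self, eeg_sim, timeline):
        rec, truth = eeg_sim
        onsets = eeg.detect_sync_events(rec.sync, rec.sfreq)
        assert len(onsets) == len(timeline.events)
        err = np.abs(np.asarray(onsets) - np.asarray(truth["sync_onsets"]))
        assert err.max() <= 1
        assert np.all(np.diff(onsets) > 0)


class TestPreprocess:
    def test_average_reference_identity(self, eeg_sim):
        rec, _ = eeg_sim
        clean = eeg.preprocess(rec)
        assert np.abs(clean.data.mean(axis=0)).max() < 1e-9

    def test_dc_offset_removed(self):
        sig = {c: np.full(int(30 * FS), 100.0) + _sine(10, 5) for c in
               ["F7", "F8", "Fz", "C3", "Cz", "Oz"]}
        clean = eeg.preprocess(_recording(sig), remove_blinks=False)
        assert abs(clean.data.mean()) < 0.5

    def test_too_few_channels_rejected(self, eeg_sim):
        rec, _ = eeg_sim
        with pytest.raises(ValueError, match="4 good channels"):
            eeg.preprocess(rec, bad_channels=rec.channels[:-3])

    def test_blink_component_removed(self, timeline):
        """Frontal low-frequency variance drops by >= 50% once the ICA
        blink component is projected out."""
        from scipy import signal as sg

        cfg = syn.SimConfig(seed=8)
        cfg.eeg.artifact_rate_hz = 0.0
        rec, truth = syn.simulate_eeg("P001", timeline, cfg)
        assert len(truth["blink_times"]) > 0

        def frontal_low_var(r):
            idx = [r.channels.index(c) for c in ("F7", "F8", "Fz")]
            sos = sg.butter(4, [0.5 / 64, 4 / 64], btype="band", output="sos")
            return sg.sosfiltfilt(sos, r.data[idx], axis=1).var(axis=1).mean()

        with_blinks = eeg.preprocess(rec, remove_blinks=False)
        without = eeg.preprocess(rec, remove_blinks=True)
        assert any("blink" in h for h in without.history)
        assert frontal_low_var(without) < 0.5 * frontal_low_var(with_blinks)


class TestArtifactMask:
    def test_constant_high_amplitude_flagged(self):
        x = np.zeros(int(30 * FS))
        x[1000:1200] = 500.0
        mask = eeg.mark_artifacts(_recording({"Cz": x}))
        assert mask[0, 1000:1200].all()

    def test_small_alpha_sine_unflagged(self):
        """10 uV 10 Hz sine: alpha Hilbert envelope ~ 10 uV < 40."""
        mask = eeg.mark_artifacts(_recording({"Cz": _sine(10, 10)}))
        assert not mask.any()

    def test_large_alpha_sine_flagged_by_envelope(self):
        """50 uV 10 Hz sine: alpha envelope ~ 50 uV > 40 though the raw
        amplitude is far below the 400 uV rules."""
        mask = eeg.mark_artifacts(_recording({"Cz": _sine(10, 50)}))
        assert mask[0].mean() > 0.9

    def test_all_zero_yields_all_false(self):
        mask = eeg.mark_artifacts(_recording({"Cz": np.zeros(int(10 * FS))}))
        assert not mask.any()

    def test_threshold_monotonicity(self, eeg_sim):
        rec, _ = eeg_sim
        base = eeg.mark_artifacts(rec)
        relaxed = eeg.mark_artifacts(
            rec, abs_threshold=800, p2p_threshold=800, envelope_threshold=80
        )
        assert relaxed.sum() <= base.sum()
        # relaxed mask is a subset of the base mask
        assert not (relaxed & ~base).any()

    def test_injected_artifacts_recovered(self, eeg_sim):
        """Ground-truth artifact segments are recalled at >= 0.9."""
        rec, truth = eeg_sim
        segments = truth["artifact_segments"]
        assert segments, "fixture should contain injected artifacts"
        clean = eeg.preprocess(rec)
        mask = eeg.mark_artifacts(clean).any(axis=0)
        hits = 0
        for a, b in segments:
            i0, i1 = int(a * FS), int(b * FS)
            hits += mask[i0:i1].mean() > 0.5
        assert hits / len(segments) >= 0.9


def _events(onsets, dur=1.0):
    return pd.DataFrame(
        [(o, dur, "emotional_memory", "n/a") for o in onsets],
        columns=["onset", "duration", "trial_type", "stimulus_valence"],
    )


class TestFeatures:
    def test_sine_rms_identity(self):
        """Pure 10 Hz sine of amplitude A: alpha RMS ~ A/sqrt(2), theta and
        beta RMS ~ 0."""
        A = 12.0
        sig = {c: _sine(10, A) for c in ["F7", "F8", "Fz", "Oz"]}
        rec = _recording(sig)
        mask = np.zeros(rec.data.shape, dtype=bool)
        row = eeg.extract_event_features(rec, mask, _events([5.0, 10.0, 15.0]))
        assert row["F_alpha_rms"] == pytest.approx(A / np.sqrt(2), rel=0.05)
        assert row["F_theta_rms"] < 0.05 * A
        assert row["F_beta_rms"] < 0.05 * A

    def test_white_noise_hurst_near_half(self, rng):
        sig = {c: rng.standard_normal(int(30 * FS)) for c in ["F7", "F8", "Fz", "Oz"]}
        rec = _recording(sig)
        mask = np.zeros(rec.data.shape, dtype=bool)
        row = eeg.extract_event_features(
            rec, mask, _events(np.arange(2.0, 28.0, 1.5))
        )
        assert row["F_hurst"] == pytest.approx(0.5, abs=0.1)

    def test_identical_channels_zero_asymmetry(self, rng):
        x = rng.standard_normal(int(20 * FS))
        rec = _recording({"F7": x, "F8": x, "Fz": x, "Oz": x})
        mask = np.zeros(rec.data.shape, dtype=bool)
        row = eeg.extract_event_features(rec, mask, _events([5.0, 10.0]))
        assert row["asym_F7_F8"] == pytest.approx(0.0, abs=1e-12)

    def test_feature_count_entering_pca(self, eeg_sim):
        rec, _ = eeg_sim
        clean = eeg.preprocess(rec)
        mask = eeg.mark_artifacts(clean)
        row = eeg.extract_event_features(clean, mask, _events([5.0, 10.0, 15.0]))
        scalar = [k for k in row if not k.startswith("asym_")]
        assert len(scalar) == 24
        assert len(eeg.SCALAR_FEATURES) * len(eeg.DEFAULT_GROUPS) == 24

    def test_masked_windows_dropped(self, rng):
        x = rng.standard_normal(int(20 * FS))
        rec = _recording({"F7": x, "F8": x, "Fz": x, "Oz": x})
        mask = np.ones(rec.data.shape, dtype=bool)  # everything contaminated
        row = eeg.extract_event_features(rec, mask, _events([5.0]))
        assert row == {} or all(k.startswith("asym") for k in row)

    def test_sample_shift_invariance(self, rng):
        """Shifting signal and events together by whole samples leaves the
        features essentially unchanged (filter edges aside)."""
        x = rng.standard_normal(int(30 * FS))
        shift = 64
        rec_a = _recording({"F7": x, "F8": x[::-1], "Fz": x, "Oz": x})
        rec_b = _recording(
            {"F7": np.roll(x, shift), "F8": np.roll(x[::-1], shift),
             "Fz": np.roll(x, shift), "Oz": np.roll(x, shift)}
        )
        mask = np.zeros(rec_a.data.shape, dtype=bool)
        ev_a = _events([10.0, 14.0])
        ev_b = _events([10.0 + shift / FS, 14.0 + shift / FS])
        row_a = eeg.extract_event_features(rec_a, mask, ev_a)
        row_b = eeg.extract_event_features(rec_b, mask, ev_b)
        for k in row_a:
            assert row_a[k] == pytest.approx(row_b[k], rel=1e-4, abs=1e-6)


class TestPCA:
    def _table(self, rng, n=30, p=24, rank=None):
        if rank is None:
            X = rng.standard_normal((n, p))
        else:
            X = rng.standard_normal((n, rank)) @ rng.standard_normal((rank, p))
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])

    def test_rank_deficient_trailing_components(self, rng):
        res = eeg.reduce_pca(self._table(rng, rank=2), k=5)
        assert res.explained_variance_ratio[2:].max() < 1e-9

    def test_loadings_orthonormal(self, rng):
        res = eeg.reduce_pca(self._table(rng), k=5)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-9)

    def test_explained_variance_nonincreasing(self, rng):
        res = eeg.reduce_pca(self._table(rng), k=5)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_row_permutation_equivariance(self, rng):
        table = self._table(rng)
        perm = rng.permutation(len(table))
        a = eeg.reduce_pca(table, k=3).scores.to_numpy()
        b = eeg.reduce_pca(table.iloc[perm].reset_index(drop=True), k=3).scores.to_numpy()
        np.testing.assert_allclose(a[perm], b, atol=1e-8)

    def test_k_exceeding_support_warns_and_truncates(self, rng):
        table = self._table(rng, n=5, p=3)
        res = eeg.reduce_pca(table, k=4)
        assert res.scores.shape[1] == 3
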