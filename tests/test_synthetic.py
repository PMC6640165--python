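"""Generator contracts: determinism, effect fidelity, structural validity."""

import numpy as np
import pandas as pd
import pytest

from affectpipe import synthetic as syn


class TestCohort:
    def test_same_seed_bit_identical(self, small_config):
        a = syn.generate_cohort(small_config)
        b = syn.generate_cohort(small_config)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_null_effects_mean_change_near_zero(self):
        cfg = syn.SimConfig(
            n_participants=1000,
            seed=1,
            self_report_effects={m: (0.0, 0.0) for m in syn.SELF_REPORT_MEASURES},
        )
        cohort = syn.generate_cohort(cfg)
        diff = cohort.post - cohort.pre
        for arm in (0, 1):
            sub = diff[cohort.condition == arm]
            se = sub.std() / np.sqrt(len(sub))
            assert (sub.mean().abs() < 3 * se).all()

    def test_default_effects_match_calibration(self):
        """Large-n standardized mean changes converge to the configured
        per-arm values (checked on the largest few effects)."""
        cohort = syn.generate_cohort(syn.SimConfig(n_participants=10000, seed=2))
        diff = cohort.post - cohort.pre
        for measure in ("Gratitude", "Negative Social Emotions", "Positive Affect"):
            for arm in (0, 1):
                sub = diff.loc[cohort.condition == arm, measure]
                target = syn.SELF_REPORT_EFFECTS[measure][arm]
                se = sub.std() / np.sqrt(len(sub))
                assert abs(sub.mean() - target) < 3 * se

    def test_condition_ratio_and_coding(self, cohort, small_config):
        assert set(cohort.condition.unique()) == {0, 1}
        n_pos = int(round(small_config.condition_ratio * small_config.n_participants))
        assert cohort.condition.sum() == n_pos

    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        cfg = syn.SimConfig(
            self_report_effects={"a": (0, 0), "b": (0, 0), "c": (0, 0)},
            measure_correlation=bad,
        )
        with pytest.raises(syn.ConfigError, match="positive semi-definite"):
            syn.generate_cohort(cfg)

    def test_default_correlation_is_psd_with_unit_diagonal(self):
        R = syn.default_measure_correlation(list(syn.SELF_REPORT_MEASURES))
        assert np.allclose(np.diag(R), 1.0)
        assert np.linalg.eigvalsh(R).min() > 0


class TestCognitiveLogs:
    def test_degenerate_probabilities(self, cohort):
        cfg = syn.SimConfig(
            n_participants=12, seed=3,
            recognition_probs={v: (1.0, 0.0) for v in syn.VALENCES},
        )
        logs = syn.simulate_cognitive_logs(cohort, cfg)
        rec = logs["recognition"]
        assert rec.loc[rec["is_old"], "clicked"].all()
        assert not rec.loc[~rec["is_old"], "clicked"].any()

    def test_recognition_cell_structure(self, cognitive_logs):
        rec = cognitive_logs["recognition"]
        counts = rec.groupby(["participant_id", "session", "valence", "is_old"]).size()
        assert (counts == 16).all()

    def test_word_find_orders_are_permutations(self, cognitive_logs):
        wf = cognitive_logs["word_find"]
        for _, g in wf.groupby(["participant_id", "session"]):
            assert sorted(g["find_order"]) == list(range(1, 10))
            ordered = g.sort_values("find_order")
            assert ordered["find_time_ms"].is_monotonic_increasing

    def test_empirical_rates_match_nominal(self):
        cfg = syn.SimConfig(
            n_participants=60, seed=4,
            recognition_probs={v: (0.75, 0.25) for v in syn.VALENCES},
        )
        cohort = syn.generate_cohort(cfg)
        rec = syn.simulate_cognitive_logs(cohort, cfg)["recognition"]
        old = rec[rec["is_old"]]
        new = rec[~rec["is_old"]]
        for frame, p in ((old, 0.75), (new, 0.25)):
            n = len(frame)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(frame["clicked"].mean() - p) < 3 * se

    def test_construal_ratings_in_range(self, cognitive_logs):
        con = cognitive_logs["construal"]
        assert con["rating"].between(1, 7).all()
        assert (con["reaction_time_s"] > 0).all()


class TestEEGSimulation:
    def test_clean_configuration_bounded(self, timeline):
        cfg = syn.SimConfig(seed=5)
        cfg.eeg.blink_rate_hz = 0.0
        cfg.eeg.artifact_rate_hz = 0.0
        rec, _ = syn.simulate_eeg("P000", timeline, cfg)
        assert np.abs(rec.data).max() < 400.0

    def test_sync_pulse_at_expected_sample(self):
        cfg = syn.SimConfig(seed=6)
        tl = syn.EventTimeline(
            pd.DataFrame(
                [(10.0, 1.0, "emotional_memory", "pos")],
                columns=["onset", "duration", "trial_type", "stimulus_valence"],
            )
        )
        rec, truth = syn.simulate_eeg("P000", tl, cfg, duration_s=20.0)
        assert abs(truth["sync_onsets"][0] - 1280) <= 1
        first_high = int(np.flatnonzero(rec.sync > 0)[0])
        assert abs(first_high - 1280) <= 1

    def test_timeline_beyond_duration_rejected(self, timeline, small_config):
        with pytest.raises(ValueError, match="beyond"):
            syn.simulate_eeg("P000", timeline, small_config, duration_s=1.0)

    def test_determinism(self, timeline, small_config):
        a, _ = syn.simulate_eeg("P003", timeline, small_config)
        b, _ = syn.simulate_eeg("P003", timeline, small_config)
        np.testing.assert_array_equal(a.data, b.data)


class TestWristbandSimulation:
    def test_constant_rr_without_modulation(self, timeline):
        cfg = syn.SimConfig(seed=8)
        cfg.ans.lf_depth_ms = 0.0
        cfg.ans.hf_depth_ms = 0.0
        cfg.ans.rr_noise_ms = 0.0
        streams, _ = syn.simulate_wristband("P000", timeline, cfg)
        assert np.allclose(streams.rr_ms, 800.0)

    def test_negative_depth_rejected(self, timeline):
        cfg = syn.SimConfig(seed=8)
        cfg.ans.hf_depth_ms = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            syn.simulate_wristband("P000", timeline, cfg)

    def test_hf_power_scales_with_depth_squared(self, timeline):
        """Doubling the HF modulation depth quadruples the recovered HF
        band power (Parseval)."""
        from affectpipe import ans

        powers = {}
        for depth in (20.0, 40.0):
            cfg = syn.SimConfig(seed=9)
            cfg.ans.hf_depth_ms = depth
            cfg.ans.lf_depth_ms = 0.0
            cfg.ans.rr_noise_ms = 0.0
            streams, _ = syn.simulate_wristband("P000", timeline, cfg)
            _, rr = ans.interpolate_rr(streams.beat_times, streams.rr_ms)
            powers[depth] = ans.hrv_band_power(rr, ans.HF_BAND)
        ratio = powers[40.0] / powers[20.0]
        assert abs(ratio - 4.0) < 0.8

    def test_determinism(self, timeline, small_config):
        a, _ = syn.simulate_wristband("P004", timeline, small_config)
        b, _ = syn.simulate_wristband("P004", timeline, small_config)
        np.testing.assert_array_equal(a.rr_ms, b.rr_ms)
        np.testing.assert_array_equal(a.gsr_phasic, b.gsr_phasic)


class TestRoundTrips:
    def test_dataset_files_round_trip(self, tmp_path, small_config):
        cfg = syn.SimConfig(n_participants=4, seed=10)
        cfg.timeline_sizes = (6, 4, 2)
        manifest = syn.write_dataset(cfg, tmp_path, physio_participants=1)
        cohort = syn.read_cohort(tmp_path / "cohort.csv")
        assert cohort.pre.shape == (4, 14)
        pdir = tmp_path / "physio" / "P000_pre"
        tl = syn.EventTimeline.read_tsv(pdir / "events.tsv")
        assert len(tl.events) == 12
        rec = syn.read_eeg_csv(pdir / "eeg.csv")
        assert rec.data.shape[0] == 12 and rec.sync is not None
        streams = syn.WristbandStreams.read_csvs(pdir)
        assert len(streams.rr_ms) == len(streams.beat_times)
        assert "P000_pre" in manifest["physio"]

    def test_timeline_invariants(self, timeline):
        onsets = timeline.events["onset"].to_numpy()
        assert np.all(np.diff(onsets) > 0)
        assert (timeline.events["duration"] > 0).all()
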