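import dataclasses

import numpy as np
import pandas as pd
import pytest

from hybridphase import detector, synth
from hybridphase.preproc import HemoSeries

from conftest import gate_frame


class TestDetectEvents:
    def test_ray_fixture_reports_half_second_latency(self, ray_series):
        """Q4 ray with R2 crossed at 1.0 s and R1 at 1.5 s: latency 0.5 s,
        command issued at the R1 crossing (1.5 s)."""
        h, v = ray_series
        r1 = 1.5 * v * np.sqrt(10.0) / 3.0  # magnitude of the ray at t = 1.5 s
        recs = detector.detect_events(h, gate_frame([1.0]), r1)
        (rec,) = recs
        assert rec.decision == "detected"
        assert rec.r2_cross_time == pytest.approx(1.0, abs=1e-9)
        assert rec.r1_cross_time == pytest.approx(1.5, abs=1e-9)
        assert rec.latency == pytest.approx(0.5, abs=1e-9)
        assert rec.command_time == pytest.approx(1.5, abs=1e-9)

    def test_no_gate_events_no_detection(self, ray_series):
        h, _ = ray_series
        recs = detector.detect_events(h, gate_frame([]), r1=1e-4)
        assert recs == []

    def test_crossings_ordered_gate_r2_r1(self, ray_series):
        h, v = ray_series
        recs = detector.detect_events(h, gate_frame([1.0]), 1.5 * v * np.sqrt(10) / 3)
        rec = recs[0]
        assert rec.gate_time <= rec.r2_cross_time <= rec.r1_cross_time

    def test_second_quadrant_excursion_not_detected(self):
        """A trajectory exceeding R1 with dHbO < 0 never triggers."""
        rate = 9.19
        t = np.arange(int(5 * rate)) / rate
        h = HemoSeries(-1e-3 * t, 1e-3 * t, rate)  # Q2 ray
        recs = detector.detect_events(h, gate_frame([1.0]), r1=1e-4)
        assert all(r.decision == "not-detected" for r in recs)

    def test_inverted_circles_still_detect_at_r1_crossing(self, ray_series):
        """If the EEG-window circle is larger than R1, the R1 crossing
        (which precedes the R2 crossing) still completes the detection."""
        h, v = ray_series
        m = lambda tt: v * tt * np.sqrt(10.0) / 3.0
        r1 = m(0.5)  # smaller than the computed r2 (~m(0.98))
        recs = detector.detect_events(h, gate_frame([1.0]), r1)
        rec = recs[0]
        assert rec.decision == "detected"
        assert rec.r2 > r1
        # eligibility completes the moment the (larger) EEG circle is crossed
        assert rec.r1_cross_time == pytest.approx(rec.r2_cross_time, abs=1e-9)

    def test_timeout_expires_unresolved_gates(self, ray_series):
        h, v = ray_series
        r1 = v * 4.6 * np.sqrt(10) / 3  # crossing would occur at 4.6 s
        recs = detector.detect_events(h, gate_frame([1.0]), r1, timeout_s=3.0)
        assert recs[0].decision == "not-detected"
        assert recs[0].r1_cross_time is None

    def test_flat_baseline_radius_rejected(self, ray_series):
        h, _ = ray_series
        with pytest.raises(ValueError, match="nonconstant"):
            detector.detect_events(h, gate_frame([1.0]), r1=0.0)

    def test_per_trial_wrapper_assigns_trial_ids(self, ray_series):
        from hybridphase.hrf import ParadigmSchedule

        h, v = ray_series
        sched = ParadigmSchedule.block_design(
            n_trials=1, task_s=2.0, rest_s=2.0, pre_rest_s=0.5, post_rest_s=0.5,
            rate=9.19,
        )
        r1 = 1.5 * v * np.sqrt(10) / 3
        recs = detector.detect(h, gate_frame([1.0]), r1, schedule=sched)
        assert len(recs) == 1
        assert recs[0].trial_id == 0
        assert recs[0].decision == "detected"


class TestTrialScoring:
    @pytest.mark.parametrize(
        "n_correct,n_total,expected",
        [(10, 12, 83.3), (11, 12, 91.7), (12, 12, 100.0), (0, 12, 0.0), (20, 24, 83.3)],
    )
    def test_accuracy_reported_to_one_decimal(self, n_correct, n_total, expected):
        assert detector.accuracy_pct(n_correct, n_total) == expected

    def test_empty_outcome_set_rejected(self):
        with pytest.raises(ValueError):
            detector.accuracy_pct(0, 0)

    def test_classify_trials_requires_records(self, default_session):
        with pytest.raises(ValueError):
            detector.classify_trials([], default_session.schedule)

    def test_gate_precedence_silent_eeg_forces_all_rest(self, default_session):
        """No EEG means no gates means no commands, whatever the fNIRS does."""
        ses = default_session
        silent = dataclasses.replace(ses, eeg=ses.eeg.assign(
            **{c: 0.0 for c in ses.eeg.columns if c.startswith("e")}
        ))
        res = detector.run_hybrid_session(silent, with_lda=False)
        assert res["n_gate_events"] == 0
        assert all(o.predicted == "rest" for o in res["outcomes"])
        assert res["accuracy_pct"] == 50.0


class TestPipeline:
    def test_default_session_detects_most_trials(self, default_run):
        res = default_run
        assert res["electrodes"] == (1, 4)
        assert set(res["channels"]) == {5, 6, 8, 9, 17, 18, 20, 21, 29, 30, 32, 33}
        assert res["accuracy_pct"] >= 75.0
        assert 0.0 < res["mean_latency_s"] < 3.0

    def test_detection_rate_monotone_in_response_amplitude(self):
        """An amplitude ladder never decreases the per-trial detection rate."""
        rates = []
        for amp in (1e-4, 1e-3, 5e-3):
            hits = 0
            for seed in (21, 22):
                ses = synth.generate_session(
                    synth.SessionSpec(seed=seed, response_peak_mM=amp)
                )
                res = detector.run_hybrid_session(ses, with_lda=False)
                hits += sum(
                    o.correct for o in res["outcomes"] if o.truth == "task"
                )
            rates.append(hits / 24)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.8

    def test_false_crossing_rate_with_forced_gates(self):
        """No-activation session, gates forced open once per second: the
        fraction of gates that complete a false detection stays <= 5%."""
        from hybridphase import phase, preproc

        spec = synth.SessionSpec(seed=31, active_channel_ids=())
        ses = synth.generate_session(spec)
        base = (0, int(60 * 9.19))
        gates = gate_frame(np.arange(61.0, 420.0, 1.0))
        n_det = n_tot = 0
        for ch in range(1, 13):
            r690, r830 = ses.intensity_pair(ch)
            h = preproc.bandpass_hemo(
                preproc.od_to_hemo(
                    preproc.intensity_to_od(r690, base),
                    preproc.intensity_to_od(r830, base),
                    rate=9.19, channel_id=ch,
                )
            )
            r1 = phase.resting_radius(h.slice_seconds(0, 60))
            recs = detector.detect_events(h, gates, r1)
            n_det += sum(r.decision == "detected" for r in recs)
            n_tot += len(recs)
        assert n_det / n_tot <= 0.05


class TestLdaBaseline:
    def test_perfectly_separated_features_score_100(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (12, 3)), rng.normal(5, 0.1, (12, 3))])
        y = np.repeat([0, 1], 12)
        assert detector.lda_baseline(X, y) == 100.0

    def test_identical_class_distributions_score_near_chance(self):
        """Permutation oracle: with labels carrying no information the
        LOO accuracy hovers around 50% (n = 24 windows)."""
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(25):
            X = rng.standard_normal((24, 4))
            y = np.repeat([0, 1], 12)
            accs.append(detector.lda_baseline(X, y))
        assert np.mean(accs) == pytest.approx(50.0, abs=10.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            detector.lda_baseline(np.zeros((10, 2)), np.zeros(10))

    def test_high_dimensional_features_fall_back_to_shrinkage(self, caplog):
        import logging

        rng = np.random.default_rng(2)
        X = rng.standard_normal((24, 30))
        y = np.repeat([0, 1], 12)
        with caplog.at_level(logging.INFO, logger="hybridphase.detector"):
            detector.lda_baseline(X, y)
        assert any("shrinkage" in r.message for r in caplog.records)

    def test_hybrid_beats_lda_on_default_session(self, default_run):
        assert default_run["accuracy_pct"] > default_run["lda_accuracy_pct"]
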