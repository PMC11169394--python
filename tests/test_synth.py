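"""Synthetic generator: waveforms, ground-truth rules, cohort simulation."""

import numpy as np
import pytest

from epiquant import (
    BaselineEstimate,
    CohortConfig,
    DetectionConfig,
    ScenarioConfig,
    ScenarioError,
    default_scenario,
    make_background,
    run_detection,
    score_detection,
    simulate_cohort,
    simulate_recording,
)
from epiquant.synth import (
    ArtifactSpec,
    EventSpec,
    SeizureSpec,
    inject_interictal_event,
    inject_seizure,
    inject_spike,
)

from conftest import make_record


class TestBackground:
    def test_sample_sd_matches_requested_sigma(self):
        rec = make_background(600.0, noise_sigma=50.0, seed=1)
        sds = rec.samples.std(axis=1)
        assert np.all((47.0 <= sds) & (sds <= 53.0))

    def test_band_limited_to_acquisition_cutoff(self):
        rec = make_background(60.0, noise_sigma=50.0, seed=2, n_channels=1)
        f = np.fft.rfftfreq(rec.n_samples, 1 / rec.fs)
        power = np.abs(np.fft.rfft(rec.samples[0])) ** 2
        assert power[f > 101.0].sum() < 1e-9 * power.sum()

    def test_seeded_determinism(self):
        a = make_background(30.0, seed=42)
        b = make_background(30.0, seed=42)
        assert np.array_equal(a.samples, b.samples)

    def test_channels_independent(self):
        rec = make_background(120.0, seed=3)
        r = np.corrcoef(rec.samples[0], rec.samples[1])[0, 1]
        assert abs(r) < 0.1

    def test_zero_duration_rejected(self):
        with pytest.raises(ScenarioError):
            make_background(0.0)


class TestInjection:
    def test_spike_peak_equals_amplitude_on_zero_background(self):
        rec = make_record()
        inject_spike(rec, "EEG1", 30.0, 600.0, 40.0)
        trace = rec.samples[0]
        assert np.abs(trace).max() == pytest.approx(600.0)
        assert abs(np.argmax(np.abs(trace)) / rec.fs - 30.0) < 1e-6

    def test_waveforms_sum_linearly(self):
        a = make_record()
        inject_spike(a, "EEG1", 30.0, 600.0, 40.0)
        b = make_record()
        inject_spike(b, "EEG1", 30.03, 600.0, 40.0)
        both = make_record()
        inject_spike(both, "EEG1", 30.0, 600.0, 40.0)
        inject_spike(both, "EEG1", 30.03, 600.0, 40.0)
        assert np.allclose(both.samples, a.samples + b.samples)

    def test_super_threshold_amplitude_logged_as_artifact(self):
        rec = make_record()
        _, ann = inject_spike(rec, "EEG1", 30.0, 2000.0, 40.0)
        assert ann.kind == "artifact"

    def test_out_of_record_placement_rejected(self):
        with pytest.raises(ScenarioError):
            inject_spike(make_record(duration=10.0), "EEG1", 9.999, 600.0, 40.0)

    @pytest.mark.parametrize(
        "n,isi,expect_events", [(5, 2.0, 1), (3, 2.0, 0), (5, 12.0, 0)]
    )
    def test_event_truth_rules(self, n, isi, expect_events):
        from epiquant.io import AnnotationSet

        rec = make_record(duration=120.0)
        truth = AnnotationSet()
        inject_interictal_event(rec, "EEG1", 30.0, n, isi, 8.0, 50.0, truth=truth)
        assert len(truth.of_kind("interictal_event")) == expect_events
        assert len(truth.of_kind("spike")) == n

    def test_dense_long_train_truth_is_seizure_not_event(self):
        from epiquant.io import AnnotationSet

        rec = make_record(duration=120.0)
        truth = AnnotationSet()
        inject_interictal_event(rec, "EEG1", 30.0, 41, 0.3, 8.0, 50.0, truth=truth)
        assert len(truth.of_kind("seizure")) == 1
        assert len(truth.of_kind("interictal_event")) == 0

    def test_seizure_truth_spike_count(self):
        from epiquant.io import AnnotationSet

        rec = make_record(duration=120.0)
        truth = AnnotationSet()
        inject_seizure(rec, "EEG1", 30.0, 12.0, 0.3, 8.0, 50.0, truth=truth)
        assert len(truth.of_kind("spike")) == 41  # floor(12/0.3)+1
        assert len(truth.of_kind("seizure")) == 1

    def test_short_seizure_truth_demoted_to_event(self):
        from epiquant.io import AnnotationSet

        rec = make_record(duration=120.0)
        truth = AnnotationSet()
        inject_seizure(rec, "EEG1", 30.0, 8.0, 0.5, 8.0, 50.0, truth=truth)
        assert len(truth.of_kind("seizure")) == 0
        assert len(truth.of_kind("interictal_event")) == 1

    def test_postictal_window_suppressed(self):
        rec = make_background(120.0, noise_sigma=50.0, seed=9, n_channels=1)
        pre = np.abs(rec.samples[0][: int(30 * rec.fs)]).mean()
        inject_seizure(
            rec, "EEG1", 40.0, 15.0, 0.3, 8.0, 50.0, postictal=True
        )
        end = 40.0 + 15.0
        post = np.abs(
            rec.samples[0][int((end + 0.1) * rec.fs) : int((end + 10) * rec.fs)]
        ).mean()
        assert post < 0.5 * pre


class TestScenario:
    def test_default_scenario_truth_counts(self):
        _, truth = simulate_recording(default_scenario(seed=0))
        counts = truth.counts()
        assert counts["interictal_event"] == 3
        assert counts["seizure"] == 1
        assert counts["artifact"] == 4  # two artifacts on two channels

    def test_seed_changes_noise_not_truth(self):
        rec_a, truth_a = simulate_recording(default_scenario(seed=0))
        rec_b, truth_b = simulate_recording(default_scenario(seed=1))
        assert truth_a.counts() == truth_b.counts()
        assert not np.array_equal(rec_a.samples, rec_b.samples)

    def test_same_seed_reproduces_exactly(self):
        rec_a, truth_a = simulate_recording(default_scenario(seed=5))
        rec_b, truth_b = simulate_recording(default_scenario(seed=5))
        assert np.array_equal(rec_a.samples, rec_b.samples)
        assert truth_a.annotations == truth_b.annotations

    def test_overlapping_seizures_rejected(self):
        sc = ScenarioConfig(
            duration=300.0,
            seizures=[
                SeizureSpec(50.0, 20.0, 0.3, 8.0),
                SeizureSpec(60.0, 20.0, 0.3, 8.0),
            ],
        )
        with pytest.raises(ScenarioError):
            simulate_recording(sc)

    def test_planted_item_outside_record_rejected(self):
        sc = ScenarioConfig(
            duration=100.0,
            events=[EventSpec(95.0, 5, 2.0, 8.0)],
        )
        with pytest.raises(ScenarioError):
            simulate_recording(sc)

    def test_noiseless_render_consistent_with_detector(self):
        """Planted truth equals detection output when noise is absent."""
        sc = ScenarioConfig(
            duration=600.0,
            noise_sigma=0.0,
            reference_sigma=50.0,
            n_isolated_spikes=5,
            events=[EventSpec(100.0, 5, 2.0, 8.0), EventSpec(200.0, 6, 6.0, 8.0)],
            seizures=[SeizureSpec(400.0, 15.0, 0.3, 8.0)],
            artifacts=[ArtifactSpec(550.0, 2000.0)],
            seed=11,
        )
        rec, truth = simulate_recording(sc)
        ann = run_detection(
            rec,
            DetectionConfig(highpass_cutoff=None),
            baseline=BaselineEstimate(amplitude=50.0, method="fixed"),
        )
        scores = score_detection(ann, truth.annotations)
        for kind in ("spike", "interictal_event", "seizure", "artifact"):
            assert scores[kind].precision == 1.0, kind
            assert scores[kind].recall == 1.0, kind


class TestCohort:
    def test_zero_incidence_means_no_seizures(self):
        cfg = CohortConfig(
            seizure_incidence={"TBI": 0.0, "T+N": 0.0}, seed=1
        )
        ds = simulate_cohort(cfg)
        assert ds.weekly.n_seizures.sum() == 0
        assert not ds.animals.seizes.any()

    def test_zero_rates_mean_zero_counts(self):
        cfg = CohortConfig(
            weekly_event_rate={"TBI": [0.0] * 12, "T+N": [0.0] * 12}, seed=2
        )
        ds = simulate_cohort(cfg)
        assert ds.weekly.n_events.sum() == 0

    def test_onset_restricted_to_monitoring_window(self):
        ds = simulate_cohort(CohortConfig(seed=3))
        onsets = ds.animals.loc[ds.animals.seizes, "onset_week"]
        assert (onsets >= 3).all()

    def test_recorded_hours_follow_schedule(self):
        cfg = CohortConfig()
        assert cfg.recorded_hours(1) == 7 * 24.0
        assert cfg.recorded_hours(2) == 24.0 + 4 * 9.0  # day 7 continuous
        assert cfg.recorded_hours(5) == 5 * 9.0

    def test_parameter_recovery_at_scale(self):
        """Empirical incidence and weekly rates recover configured values."""
        cfg = CohortConfig(
            n_per_group={"TBI": 200, "T+N": 200}, seed=17
        )
        ds = simulate_cohort(cfg)
        tbi = ds.animals[ds.animals.group == "TBI"]
        assert abs(tbi.seizes.mean() - 0.71) <= 0.05
        tn = ds.animals[ds.animals.group == "T+N"]
        assert tn.seizes.mean() == 0.0
        # rate MLE per week, rescaled to the reference 45-h exposure
        weekly = ds.group_weekly("TBI")
        for week in (1, 6, 12):
            rows = weekly[weekly.week == week]
            scale = rows.recorded_hours / cfg.reference_hours
            mle = rows.n_events.sum() / scale.sum()
            target = cfg.weekly_event_rate["TBI"][week - 1]
            assert abs(mle - target) / target < 0.10

    def test_seeded_determinism(self):
        a = simulate_cohort(CohortConfig(seed=8))
        b = simulate_cohort(CohortConfig(seed=8))
        assert a.weekly.equals(b.weekly)
        assert a.animals.equals(b.animals)

    def test_first_seizure_table_censoring(self):
        ds = simulate_cohort(CohortConfig(seed=4))
        table = ds.first_seizure_table()
        censored = table[table.event == 0]
        assert (censored.time_weeks == 12).all()
        seizing = table[table.event == 1]
        onsets = ds.animals.set_index("animal_id").onset_week
        assert all(onsets[a] == t for a, t in zip(seizing.animal_id, seizing.time_weeks))
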