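"""Baseline, spike, seizure and interictal-event detection behavior."""

import numpy as np
import pytest

from epiquant import (
    BaselineEstimate,
    DegenerateBaselineError,
    DetectionConfig,
    DetectionError,
    EEGRecord,
    detect_interictal_events,
    detect_seizures,
    detect_spikes,
    estimate_baseline,
    run_detection,
    score_detection,
)
from epiquant.io import Annotation, AnnotationSet
from epiquant.detect import Spike
from epiquant.synth import inject_plateau, inject_spike, make_background

from conftest import make_record


def spikes_at(times, amp=400.0, channel="EEG1", width=40.0):
    return [Spike(channel, float(t), amp, width) for t in times]


class TestBaseline:
    def test_gaussian_noise_sigma_recovered(self):
        # flat band-limited noise: the MAD-based estimate is a consistent
        # estimator of the Gaussian sigma
        rec = make_background(
            600.0, noise_sigma=50.0, seed=7, n_channels=1, spectral_exponent=0.0
        )
        est = estimate_baseline(rec, "EEG1")
        assert 45.0 <= est.amplitude <= 55.0

    def test_robust_to_planted_transients(self):
        rec = make_background(600.0, noise_sigma=50.0, seed=3, n_channels=1)
        clean = estimate_baseline(rec, "EEG1").amplitude
        for k in range(20):
            inject_spike(rec, "EEG1", 20.0 + 28.0 * k, 800.0, 50.0)
        spiked = estimate_baseline(rec, "EEG1").amplitude
        assert abs(spiked - clean) / clean < 0.10

    def test_flat_signal_degenerate(self):
        with pytest.raises(DegenerateBaselineError):
            estimate_baseline(make_record(duration=20.0), "EEG1")

    def test_short_record_rejected(self):
        rec = EEGRecord(samples=np.random.default_rng(0).normal(size=(1, 5000)),
                        fs=1000.0, channel_ids=("EEG1",))
        with pytest.raises(DetectionError):
            estimate_baseline(rec, "EEG1")


class TestSpikeDetection:
    def test_planted_spike_found_at_planted_time(self, baseline50, config_no_hp):
        rec = make_record()
        inject_spike(rec, "EEG1", 30.0, 600.0, 40.0)
        spikes, artifacts = detect_spikes(rec, baseline50, config_no_hp)
        assert len(spikes) == 1 and not artifacts
        assert abs(spikes[0].peak_time - 30.0) <= 0.002
        assert spikes[0].amplitude == pytest.approx(600.0, rel=0.01)

    def test_sub_minimum_height_ignored(self, baseline50, config_no_hp):
        rec = make_record()
        inject_spike(rec, "EEG1", 30.0, 150.0, 40.0)
        spikes, artifacts = detect_spikes(rec, baseline50, config_no_hp)
        assert spikes == [] and artifacts == []

    def test_super_threshold_transient_is_artifact(self, baseline50, config_no_hp):
        rec = make_record()
        inject_spike(rec, "EEG1", 30.0, 2000.0, 40.0)
        spikes, artifacts = detect_spikes(rec, baseline50, config_no_hp)
        assert spikes == []
        assert len(artifacts) == 1
        assert artifacts[0].amplitude > 1500.0

    def test_wide_plateau_rejected(self, baseline50, config_no_hp):
        rec = make_record()
        inject_plateau(rec, "EEG1", 30.0, 800.0, 500.0)
        spikes, artifacts = detect_spikes(rec, baseline50, config_no_hp)
        assert spikes == [] and artifacts == []

    def test_lower_threshold_scales_with_baseline(self, config_no_hp):
        # 2 x 150 μV baseline = 300 μV lower threshold: a 250 μV spike
        # clears the absolute 200 μV floor but not the baseline multiple
        rec = make_record()
        inject_spike(rec, "EEG1", 30.0, 250.0, 40.0)
        high_bl = BaselineEstimate(amplitude=150.0, method="fixed")
        spikes, _ = detect_spikes(rec, high_bl, config_no_hp)
        assert spikes == []

    def test_biphasic_counts_once(self, baseline50, config_no_hp):
        # the negative after-going lobe exceeds threshold but sits inside
        # the refractory window of the main peak
        rec = make_record()
        inject_spike(rec, "EEG1", 30.0, 1200.0, 60.0)
        spikes, _ = detect_spikes(rec, baseline50, config_no_hp)
        assert len(spikes) == 1


class TestSeizureDetection:
    def test_dense_12s_train_is_one_seizure(self, baseline50, config):
        spikes = spikes_at(100.0 + 0.3 * np.arange(41))
        seizures = detect_seizures(spikes, baseline50, config)
        assert len(seizures) == 1
        assert seizures[0].duration == pytest.approx(12.0, abs=0.01)
        assert len(seizures[0].spikes) == 41

    def test_8s_train_too_short(self, baseline50, config):
        spikes = spikes_at(100.0 + 0.5 * np.arange(17))
        assert detect_seizures(spikes, baseline50, config) == []

    def test_sparse_train_isi_breaks_run(self, baseline50, config):
        spikes = spikes_at(100.0 + 6.0 * np.arange(5))
        assert detect_seizures(spikes, baseline50, config) == []

    def test_empty_spike_list(self, baseline50, config):
        assert detect_seizures([], baseline50, config) == []

    def test_low_amplitude_spikes_do_not_join(self, baseline50, config):
        # amplitude below 3x baseline: dense and long but not ictal
        spikes = spikes_at(100.0 + 0.3 * np.arange(41), amp=140.0)
        assert detect_seizures(spikes, baseline50, config) == []

    def test_postictal_suppression_flag(self, baseline50, config_no_hp):
        fs = 1000.0
        rng = np.random.default_rng(5)
        trace = rng.normal(0.0, 50.0, int(140 * fs))
        end = 120.0
        trace[int(end * fs):] *= 0.3  # suppressed tail
        spikes = spikes_at(100.0 + 0.5 * np.arange(41))
        seizures = detect_seizures(
            spikes, baseline50, config_no_hp, trace=trace, fs=fs
        )
        assert len(seizures) == 1
        assert seizures[0].postictal_suppression is True


class TestInterictalEvents:
    def test_five_spikes_form_event(self, baseline50, config):
        spikes = spikes_at(50.0 + 2.0 * np.arange(5))
        events = detect_interictal_events(spikes, [], baseline50, config)
        assert len(events) == 1
        assert events[0].n_spikes == 5

    def test_three_spikes_insufficient(self, baseline50, config):
        spikes = spikes_at(50.0 + 2.0 * np.arange(3))
        assert detect_interictal_events(spikes, [], baseline50, config) == []

    def test_long_gap_splits_cluster(self, baseline50, config):
        times = list(50.0 + 2.0 * np.arange(4)) + list(71.0 + 2.0 * np.arange(4))
        events = detect_interictal_events(
            spikes_at(times), [], baseline50, config
        )
        assert [e.n_spikes for e in events] == [4, 4]

    def test_spikes_inside_seizure_masked(self, baseline50, config):
        spikes = spikes_at(100.0 + 2.0 * np.arange(6))
        seizures = detect_seizures(
            spikes_at(98.0 + 0.3 * np.arange(60)), baseline50, config
        )
        assert len(seizures) == 1
        assert detect_interictal_events(spikes, seizures, baseline50, config) == []

    def test_sub_threshold_amplitude_excluded(self, baseline50, config):
        # 3 x 50 = 150 μV floor for event membership
        spikes = spikes_at(50.0 + 2.0 * np.arange(5), amp=140.0)
        assert detect_interictal_events(spikes, [], baseline50, config) == []


class TestRunDetection:
    def test_identical_channels_merge_to_single_counts(self, baseline50, config_no_hp):
        rec = make_record(duration=120.0, n_channels=2)
        for chan in ("EEG1", "EEG2"):
            for k in range(5):
                inject_spike(rec, chan, 30.0 + 2.0 * k, 400.0, 40.0)
            for k in range(50):
                inject_spike(rec, chan, 80.0 + 0.3 * k, 400.0, 30.0)
        ann = run_detection(rec, config_no_hp, baseline=baseline50)
        counts = ann.counts()
        assert counts["interictal_event"] == 1
        assert counts["seizure"] == 1
        assert counts["spike"] == 110  # per-channel spikes are kept

    def test_degenerate_baseline_propagates(self, config):
        rec = make_record(duration=60.0)
        with pytest.raises(DegenerateBaselineError):
            run_detection(rec, config)


class TestScoring:
    def ann(self, kind, start, end, channel="EEG1"):
        return Annotation("m", channel, kind, start, end, 400.0)

    def test_identical_sets_are_perfect(self):
        a = AnnotationSet([self.ann("seizure", 10, 25), self.ann("spike", 3, 3)])
        scores = score_detection(a, a)
        assert scores["seizure"].precision == scores["seizure"].recall == 1.0
        assert scores["spike"].precision == scores["spike"].recall == 1.0

    def test_partial_match_three_of_four(self):
        truth = AnnotationSet(
            [self.ann("interictal_event", 10 * k, 10 * k + 4) for k in range(1, 5)]
        )
        detected = AnnotationSet(
            [self.ann("interictal_event", 10 * k, 10 * k + 4) for k in range(1, 4)]
            + [self.ann("interictal_event", 200, 204)]
        )
        s = score_detection(detected, truth)["interictal_event"]
        assert s.precision == pytest.approx(0.75)
        assert s.recall == pytest.approx(0.75)

    def test_empty_detection_flagged(self):
        truth = AnnotationSet([self.ann("seizure", 10, 25)])
        s = score_detection(AnnotationSet(), truth)["seizure"]
        assert s.recall == 0.0
        assert s.precision == 0.0
        assert s.undefined_precision
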