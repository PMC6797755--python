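"""Classifier, persistence filter and end-to-end detection properties."""

import numpy as np
import pytest

from wntnoise import (
    ImageStack,
    NoiseParams,
    SimConfig,
    classify_frame,
    detect,
    embryo_mask,
    persistence_filter,
    plant_exact_events,
    score_detection,
    simulate_scene,
)
from wntnoise.noise_detect import HIGH, LOW, events_to_frame, time_course_frame


def make_stack(data, interval=3.5):
    return ImageStack(np.asarray(data, dtype=float), 6.5, interval)


class TestEmbryoMask:
    def test_constant_frame_masks_fully(self, flat_frame):
        masks = embryo_mask(make_stack(flat_frame[None]))
        assert masks.all()

    def test_half_zero_half_bright_masks_bright_half(self):
        frame = np.zeros((10, 20))
        frame[:, 10:] = 100.0
        masks = embryo_mask(make_stack(frame[None]))
        assert masks[0, :, 10:].all() and not masks[0, :, :10].any()

    def test_all_zero_frame_gives_empty_mask(self):
        masks = embryo_mask(make_stack(np.zeros((1, 8, 8))))
        assert not masks.any()

    def test_disc_embryo_on_dark_background_recovered(self):
        # synthetic embryo disc on zero background: Jaccard >= 0.95
        ys, xs = np.mgrid[0:60, 0:60]
        disc = (ys - 30) ** 2 + (xs - 30) ** 2 <= 20**2
        rng = np.random.default_rng(0)
        frame = np.where(disc, 100.0 + rng.normal(0, 5, disc.shape), 0.0)
        frame = np.clip(frame, 0, None)
        masks = embryo_mask(make_stack(frame[None]), NoiseParams(mask_quantile=0.4))
        jaccard = (masks[0] & disc).sum() / (masks[0] | disc).sum()
        assert jaccard >= 0.95


class TestClassifyFrame:
    def test_constant_frame_all_none(self, flat_frame):
        labels, folds = classify_frame(flat_frame, np.ones_like(flat_frame, bool))
        assert not labels.any()
        assert np.allclose(folds, 1.0)

    @pytest.mark.parametrize(
        "value,expected_label,expected_fold",
        [(300.0, HIGH, 3.0), (40.0, LOW, 0.4)],
    )
    def test_single_outlier_pixel(self, flat_frame, value, expected_label,
                                  expected_fold):
        frame = flat_frame.copy()
        frame[10, 10] = value
        labels, folds = classify_frame(frame, np.ones_like(frame, bool))
        assert labels[10, 10] == expected_label
        assert folds[10, 10] == pytest.approx(expected_fold)
        # neighbours of the outlier stay unlabelled: their neighbourhood mean
        # moves by at most value/8, never past the two-fold threshold here
        labels[10, 10] = 0
        assert not labels.any()

    @pytest.mark.parametrize("value,fold", [(200.0, 2.0), (50.0, 0.5)])
    def test_fold_exactly_at_threshold_is_not_noise(self, value, fold):
        # strict inequalities: exactly two-fold (or half) is not noise
        frame = np.full((9, 9), 100.0)
        frame[4, 4] = value  # all 8 neighbours are 100
        labels, folds = classify_frame(frame, np.ones_like(frame, bool))
        assert folds[4, 4] == fold
        assert labels[4, 4] == 0

    def test_zero_neighbour_stat_positive_pixel_flagged_high_inf(self):
        frame = np.zeros((5, 5))
        frame[2, 2] = 7.0
        labels, folds = classify_frame(frame, np.ones((5, 5), bool))
        assert labels[2, 2] == HIGH
        assert np.isinf(folds[2, 2])
        # ring pixels see a positive neighbour mean with zero intensity: Low
        # by the strict rule; pixels with zero stat and zero intensity: none
        assert (labels == LOW).sum() == 8
        assert labels[0, 0] == 0

    def test_pixel_without_masked_neighbours_unclassified(self):
        frame = np.full((5, 5), 100.0)
        frame[2, 2] = 500.0
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True  # isolated masked pixel
        labels, _ = classify_frame(frame, mask)
        assert labels[2, 2] == 0

    def test_median_statistic_matches_manual(self):
        frame = np.full((7, 7), 100.0)
        frame[3, 3] = 300.0
        params = NoiseParams(neighbour_stat="median")
        labels, folds = classify_frame(frame, np.ones((7, 7), bool), params)
        assert folds[3, 3] == pytest.approx(3.0)  # median of 8 neighbours = 100
        assert labels[3, 3] == HIGH


class TestPersistenceFilter:
    def _calls(self, spans, n_frames=10, shape=(6, 6)):
        labels = np.zeros((n_frames, *shape), dtype=np.int8)
        folds = np.ones((n_frames, *shape))
        for (y, x, frames, cls, fold) in spans:
            for t in frames:
                labels[t, y, x] = cls
                folds[t, y, x] = fold
        return labels, folds

    def test_three_frame_run_is_one_event(self):
        labels, folds = self._calls([(2, 2, [3, 4, 5], HIGH, 3.0)])
        events, transients, dropped = persistence_filter(labels, folds)
        assert len(events) == 1 and not dropped and transients.sum() == 0
        e = events[0]
        assert (e.start_frame, e.end_frame, e.event_class, e.peak_fold) == (3, 5, "High", 3.0)

    def test_single_frame_call_is_a_transient(self):
        labels, folds = self._calls([(1, 1, [7], HIGH, 5.0)])
        events, transients, _ = persistence_filter(labels, folds)
        assert not events
        assert transients[7] == 1 and transients.sum() == 1

    def test_alternating_frames_are_three_transients(self):
        labels, folds = self._calls([(0, 0, [1], HIGH, 3.0),
                                     (0, 0, [3], HIGH, 3.0),
                                     (0, 0, [5], HIGH, 3.0)])
        events, transients, _ = persistence_filter(labels, folds)
        assert not events and transients.sum() == 3

    def test_class_switch_terminates_a_run(self):
        labels, folds = self._calls([(2, 3, [2, 3], HIGH, 3.0),
                                     (2, 3, [4, 5], LOW, 0.3)])
        events, transients, _ = persistence_filter(labels, folds)
        assert [e.event_class for e in events] == ["High", "Low"]
        assert transients.sum() == 0

    def test_two_frame_run_failing_duration_is_dropped_not_transient(self):
        labels, folds = self._calls([(1, 1, [2, 3], HIGH, 3.0)])
        # 2 frames x 2.5 min = 5 min, not > 6 min: fails duration only
        events, transients, dropped = persistence_filter(
            labels, folds, frame_interval_min=2.5
        )
        assert not events and transients.sum() == 0
        assert len(dropped) == 1 and dropped[0].run_length == 2

    def test_peak_fold_is_min_for_low_runs(self):
        labels = np.zeros((4, 3, 3), dtype=np.int8)
        folds = np.ones((4, 3, 3))
        labels[0:3, 1, 1] = LOW
        folds[0:3, 1, 1] = [0.4, 0.2, 0.3]
        events, _, _ = persistence_filter(labels, folds)
        assert events[0].peak_fold == pytest.approx(0.2)


class TestDetect:
    def test_planted_events_and_spikes_separate_exactly(self, noiseless_config):
        truth = plant_exact_events(noiseless_config, 20, 3, 3.0, 50, seed=5)
        scene = simulate_scene(noiseless_config, truth)
        stack = make_stack(scene.stack)
        events, tc = detect(stack, mask=scene.embryo_mask)
        assert len(events) == 20
        assert tc["transients"].sum() == 50
        score = score_detection(truth, events)
        assert score["recall"] == 1.0 and score["precision"] == 1.0

    def test_global_scaling_leaves_detection_unchanged(self):
        cfg = SimConfig(seed=9)
        scene = simulate_scene(cfg)
        ev1, tc1 = detect(make_stack(scene.stack))
        ev2, tc2 = detect(make_stack(scene.stack * 7.3))
        f1, f2 = events_to_frame(ev1), events_to_frame(ev2)
        cols = ["x", "y", "event_class", "start_frame", "end_frame"]
        assert f1[cols].equals(f2[cols])
        assert np.allclose(f1["peak_fold"], f2["peak_fold"], rtol=1e-9)
        assert tc1.equals(tc2)

    def test_constant_stack_yields_nothing(self):
        stack = make_stack(np.full((5, 12, 12), 42.0))
        events, tc = detect(stack)
        assert not events and tc["transients"].sum() == 0

    def test_smooth_gradient_yields_nothing(self):
        cfg = SimConfig(noise_model="none", unfit_rate=0.0, spike_rate=0.0)
        scene = simulate_scene(cfg)
        events, tc = detect(make_stack(scene.stack))
        assert not events and tc["transients"].sum() == 0

    def test_spike_amplitude_never_creates_an_event(self, noiseless_config):
        # single-frame spikes never persist, whatever their amplitude; huge
        # spikes additionally drag their ring neighbours below the Low cut for
        # that one frame, which also only ever adds transients, never events
        for fold in (2.5, 3.0, 10.0, 1000.0):
            truth = plant_exact_events(noiseless_config, 0, 3, 3.0, 30,
                                       spike_fold=fold, seed=1)
            scene = simulate_scene(noiseless_config, truth)
            events, tc = detect(make_stack(scene.stack), mask=scene.embryo_mask)
            assert not events
            assert tc["transients"].sum() >= 30
            if fold <= 9.0:  # ring mean stays under two-fold: spikes only
                assert tc["transients"].sum() == 30

    def test_counting_conservation(self):
        # sum of High+Low pixel-frames equals the sum of event run lengths
        cfg = SimConfig(seed=13)
        scene = simulate_scene(cfg)
        events, tc = detect(make_stack(scene.stack), mask=scene.embryo_mask)
        assert (tc["high_px"] + tc["low_px"]).sum() == sum(e.run_length for e in events)

    def test_too_short_stack_rejected(self):
        with pytest.raises(ValueError, match="stack too short"):
            detect(make_stack(np.full((1, 8, 8), 5.0)))

    def test_time_course_shapes(self):
        tc = time_course_frame([], np.zeros(4, int), 4)
        assert list(tc.columns) == ["frame", "high_px", "low_px", "transients"]
        assert len(tc) == 4


class TestImageStackValidation:
    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(np.full((2, 4, 4), -1.0))

    def test_wrong_dimensionality_rejected(self):
        with pytest.raises(ValueError):
            ImageStack(np.zeros((4, 4)))
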