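import numpy as np
import pytest

from crustavision import synthetic as syn
from crustavision.keypoints import KEYPOINT_NAMES
from crustavision.segmentation import ConfidenceSignal


class TestEventSchedule:
    def test_valid(self):
        s = syn.EventSchedule([(0, 10), (20, 30)], 50)
        assert s.n_events == 2

    @pytest.mark.parametrize(
        "events", [[(5, 5)], [(10, 5)], [(-1, 5)], [(0, 60)], [(0, 10), (5, 20)]]
    )
    def test_invalid(self, events):
        with pytest.raises(ValueError):
            syn.EventSchedule(events, 50)

    def test_indicator(self):
        s = syn.EventSchedule([(2, 4)], 6)
        np.testing.assert_array_equal(s.indicator(), [0, 0, 1, 1, 0, 0])

    def test_csv_round_trip(self, tmp_path):
        s = syn.EventSchedule([(3, 9), (12, 30)], 40)
        s.to_csv(tmp_path / "sched.csv")
        back = syn.EventSchedule.from_csv(tmp_path / "sched.csv", n_frames=40)
        assert back.events == s.events


class TestGenerateSignal:
    def test_noise_free_equals_indicator(self):
        sched = syn.EventSchedule([(10, 30), (50, 70)], 100)
        noise = syn.SignalNoiseModel(
            in_event_level=1.0,
            out_event_level=0.0,
            dropout_prob=0.0,
            spike_prob=0.0,
            jitter_sd=0.0,
        )
        sig = syn.generate_signal(sched, noise)
        np.testing.assert_array_equal(sig.values, sched.indicator())

    def test_deterministic(self):
        sched = syn.EventSchedule([(10, 40)], 200)
        noise = syn.SignalNoiseModel(dropout_prob=0.3, spike_prob=0.1, seed=5)
        a = syn.generate_signal(sched, noise)
        b = syn.generate_signal(sched, noise)
        np.testing.assert_array_equal(a.values, b.values)

    def test_in_event_mean_exceeds_out_event_mean(self):
        sched = syn.EventSchedule([(50, 120), (300, 380), (500, 560)], 800)
        noise = syn.SignalNoiseModel(
            dropout_prob=0.3, spike_prob=0.05, spike_amplitude=0.1, seed=3
        )
        sig = syn.generate_signal(sched, noise)
        ind = sched.indicator().astype(bool)
        assert sig.values[ind].mean() > sig.values[~ind].mean()

    def test_bounds(self):
        sched = syn.EventSchedule([(0, 50)], 100)
        noise = syn.SignalNoiseModel(jitter_sd=0.5, seed=2)
        sig = syn.generate_signal(sched, noise)
        assert sig.values.min() >= 0.0 and sig.values.max() <= 1.0

    def test_zero_frames_rejected(self):
        sched = syn.EventSchedule([], 0)
        with pytest.raises(ValueError):
            syn.generate_signal(sched, syn.SignalNoiseModel())

    def test_invalid_noise_model(self):
        with pytest.raises(ValueError):
            syn.SignalNoiseModel(in_event_level=0.2, out_event_level=0.5)
        with pytest.raises(ValueError):
            syn.SignalNoiseModel(dropout_prob=1.5)


class TestGenerateFrame:
    SIZE = (160, 90)

    def test_absent(self):
        img, ann = syn.generate_frame(present=False, image_size=self.SIZE, seed=0)
        assert not ann.present
        assert img.shape == (90, 160, 3)

    def test_deterministic(self):
        pose = syn.Pose(center=(80.0, 45.0), angle=15.0, scale=14.0)
        a, _ = syn.generate_frame(True, "top", pose, self.SIZE, seed=9)
        b, _ = syn.generate_frame(True, "top", pose, self.SIZE, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_centered_unrotated_keypoints_symmetric(self):
        pose = syn.Pose(center=(80.0, 45.0), angle=0.0, scale=12.0)
        _, ann = syn.generate_frame(True, "top", pose, self.SIZE, seed=1)
        kps = ann.keypoints
        # mirror pairs share y and are symmetric in x about the axis (x=80)
        for left, right in [("crab_left", "crab_right"), ("left_eye", "right_eye")]:
            lx, ly = kps[left]
            rx, ry = kps[right]
            assert abs(ly - ry) < 1.0
            assert abs((80.0 - lx) - (rx - 80.0)) < 1.0
        # axial points sit on the axis
        for name in ("carapace_end", "tail_end", "last_segment"):
            assert abs(kps[name][0] - 80.0) < 1.0

    def test_keypoints_inside_bbox_interior_pose(self):
        for angle in (0.0, 33.0, -120.0, 90.0):
            pose = syn.Pose(center=(80.0, 45.0), angle=angle, scale=11.0)
            _, ann = syn.generate_frame(True, "underside", pose, self.SIZE, seed=4)
            assert not ann.partial
            x, y, w, h = ann.bbox
            assert 0 <= x and x + w <= 160 and 0 <= y and y + h <= 90
            for kx, ky in ann.keypoints.values():
                assert x <= kx <= x + w
                assert y <= ky <= y + h

    def test_all_seven_keypoints_emitted(self):
        _, ann = syn.generate_frame(
            True, "top", syn.Pose(center=(80.0, 45.0)), self.SIZE, seed=0
        )
        assert set(ann.keypoints) == set(KEYPOINT_NAMES)

    def test_partial_pose_flagged_and_discounted(self):
        interior = syn.Pose(center=(80.0, 45.0), scale=12.0)
        edge = syn.Pose(center=(3.0, 45.0), scale=12.0)
        _, ann_in = syn.generate_frame(True, "top", interior, self.SIZE, seed=2)
        _, ann_edge = syn.generate_frame(True, "top", edge, self.SIZE, seed=2)
        assert ann_edge.partial and not ann_in.partial
        assert ann_edge.quality < ann_in.quality

    def test_blur_lowers_quality(self):
        sharp = syn.Pose(center=(80.0, 45.0), blur=0.0)
        blurred = syn.Pose(center=(80.0, 45.0), blur=0.7)
        _, a = syn.generate_frame(True, "top", sharp, self.SIZE, seed=2)
        _, b = syn.generate_frame(True, "top", blurred, self.SIZE, seed=2)
        assert b.quality < a.quality

    def test_views_differ(self):
        pose = syn.Pose(center=(80.0, 45.0), scale=14.0)
        top, _ = syn.generate_frame(True, "top", pose, self.SIZE, seed=5)
        under, _ = syn.generate_frame(True, "underside", pose, self.SIZE, seed=5)
        assert (top != under).any()

    def test_unknown_view(self):
        with pytest.raises(ValueError):
            syn.generate_frame(True, "side", None, self.SIZE, seed=0)


class TestGenerateVideo:
    def test_zero_events(self):
        sched = syn.EventSchedule([], 20)
        video = syn.generate_video(sched, image_size=(80, 46), seed=0)
        assert all(not a.present for a in video.annotations)

    def test_presence_runs_match_schedule(self, small_video):
        present = np.array([a.present for a in small_video.annotations])
        diff = np.diff(np.concatenate(([0], present.astype(int), [0])))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        assert list(zip(starts, ends)) == list(small_video.schedule.events)

    def test_best_frame_is_quality_argmax(self, small_video):
        for i, (s, e) in enumerate(small_video.schedule.events):
            qualities = [small_video.annotations[f].quality for f in range(s, e)]
            assert small_video.best_frames[i] == s + int(np.argmax(qualities))

    def test_deterministic(self):
        sched = syn.EventSchedule([(5, 25)], 35)
        a = syn.generate_video(sched, image_size=(80, 46), seed=3)
        b = syn.generate_video(sched, image_size=(80, 46), seed=3)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)

    def test_track_length_mismatch_rejected(self):
        sched = syn.EventSchedule([(0, 10)], 20)
        bad_track = [syn.Pose(center=(40.0, 23.0))] * 5
        with pytest.raises(ValueError):
            syn.generate_video(sched, pose_tracks=[bad_track], image_size=(80, 46))


def test_random_schedule_well_separated():
    sched = syn.random_schedule(2000, 8, seed=11)
    assert sched.n_events == 8
    assert sched.events[0][0] >= 60
    for (s1, e1), (s2, e2) in zip(sched.events[:-1], sched.events[1:]):
        assert s2 - e1 >= 60


def test_random_schedule_too_small_rejected():
    with pytest.raises(ValueError):
        syn.random_schedule(100, 5, seed=0)


def test_save_load_round_trip(tmp_path):
    sched = syn.EventSchedule([(4, 20)], 30)
    video = syn.generate_video(sched, image_size=(80, 46), seed=6)
    syn.save_video(video, tmp_path / "vid")
    back = syn.load_video(tmp_path / "vid")
    assert back.n_frames == video.n_frames
    assert back.schedule.events == video.schedule.events
    assert back.best_frames == video.best_frames
    for fa, fb in zip(video.frames, back.frames):
        np.testing.assert_array_equal(fa, fb)
    for aa, ab in zip(video.annotations, back.annotations):
        assert aa.present == ab.present
        if aa.present:
            assert aa.bbox == ab.bbox
            assert aa.view == ab.view
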