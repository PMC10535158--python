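import json

import numpy as np
import pytest

from crustavision import keypoints as kp


def brute_force_mee(predicted, truth):
    """Independent per-point loop oracle."""
    dists = []
    for p, t in zip(predicted, truth):
        for name in kp.KEYPOINT_NAMES:
            dx = p[name][0] - t[name][0]
            dy = p[name][1] - t[name][1]
            dists.append((dx * dx + dy * dy) ** 0.5)
    return sum(dists) / len(dists)


def random_keypoint_set(rng, scale=100.0):
    return kp.KeypointSet(
        {n: (rng.random() * scale, rng.random() * scale) for n in kp.KEYPOINT_NAMES}
    )


class TestKeypointSet:
    def test_seven_names(self):
        assert len(kp.KEYPOINT_NAMES) == 7

    def test_vector_round_trip_lossless(self, rng):
        original = random_keypoint_set(rng)
        back = kp.KeypointSet.from_vector(original.to_vector())
        assert back == original

    def test_vector_length_14(self, rng):
        assert random_keypoint_set(rng).to_vector().shape == (14,)

    def test_missing_name_rejected(self):
        coords = {n: (0.0, 0.0) for n in kp.KEYPOINT_NAMES[:-1]}
        with pytest.raises(ValueError, match="mismatch"):
            kp.KeypointSet(coords)

    def test_extra_name_rejected(self):
        coords = {n: (0.0, 0.0) for n in kp.KEYPOINT_NAMES}
        coords["rostrum"] = (1.0, 1.0)
        with pytest.raises(ValueError):
            kp.KeypointSet(coords)

    def test_bad_vector_length(self):
        with pytest.raises(ValueError):
            kp.KeypointSet.from_vector(np.zeros(13))


class TestMeanEuclideanError:
    def test_exact_match_zero(self, rng):
        sets = [random_keypoint_set(rng) for _ in range(3)]
        assert kp.mean_euclidean_error(sets, sets) == 0.0

    def test_uniform_3_4_offset_is_5(self, rng):
        truth = [random_keypoint_set(rng) for _ in range(4)]
        predicted = [t.translate(3.0, 4.0) for t in truth]
        assert kp.mean_euclidean_error(predicted, truth) == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self, rng):
        truth = [random_keypoint_set(rng) for _ in range(10)]
        predicted = [random_keypoint_set(rng) for _ in range(10)]
        assert kp.mean_euclidean_error(predicted, truth) == pytest.approx(
            brute_force_mee(predicted, truth)
        )

    def test_translation_invariant(self, rng):
        truth = [random_keypoint_set(rng) for _ in range(5)]
        predicted = [random_keypoint_set(rng) for _ in range(5)]
        base = kp.mean_euclidean_error(predicted, truth)
        shifted = kp.mean_euclidean_error(
            [p.translate(17.0, -4.0) for p in predicted],
            [t.translate(17.0, -4.0) for t in truth],
        )
        assert shifted == pytest.approx(base)

    def test_non_negative(self, rng):
        truth = [random_keypoint_set(rng)]
        predicted = [random_keypoint_set(rng)]
        assert kp.mean_euclidean_error(predicted, truth) >= 0.0

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            kp.mean_euclidean_error([random_keypoint_set(rng)], [])


class TestRelativeError:
    def test_forward_consistency(self):
        # 28.09 px at 5.76% implies a ~487.7 px mean animal size
        size = 100.0 * 28.09 / 5.76
        assert kp.relative_error(28.09, size) == pytest.approx(5.76)
        assert size == pytest.approx(487.7, abs=0.1)

    def test_zero_mee(self):
        assert kp.relative_error(0.0, 300.0) == 0.0

    def test_simple_ratio(self):
        assert kp.relative_error(5.0, 100.0) == pytest.approx(5.0)

    def test_non_positive_size_rejected(self):
        with pytest.raises(ValueError):
            kp.relative_error(5.0, 0.0)


class TestSpeciesKeypoints:
    def test_crab_two_names(self):
        assert len(kp.species_keypoints("crab")) == 2

    def test_lobster_five_names(self):
        assert len(kp.species_keypoints("lobster")) == 5

    def test_union_is_all_seven(self):
        union = set(kp.species_keypoints("crab")) | set(kp.species_keypoints("lobster"))
        assert union == set(kp.KEYPOINT_NAMES)

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            kp.species_keypoints("squid")


class TestKeypointRegressor:
    def test_output_dim_14(self):
        model = kp.KeypointRegressor((96, 96))
        assert model.output_dim == 14

    def test_spec_output_dim(self):
        assert kp.KeypointModelSpec().output_dim == 14

    def test_forward_emits_14_scalars(self):
        model = kp.KeypointRegressor((96, 96), seed=0)
        crop = np.zeros((96, 96), dtype=np.uint8)
        assert model.predict_vector(crop).shape == (14,)

    def test_zero_init_head_emits_bias(self):
        model = kp.KeypointRegressor((96, 96), seed=0, zero_init_head=True)
        crop = np.random.default_rng(0).integers(0, 256, (96, 96), dtype=np.uint8)
        np.testing.assert_array_equal(model.predict_vector(crop), np.zeros(14))

    def test_wrong_shape_rejected_never_resized(self):
        model = kp.KeypointRegressor((96, 96))
        with pytest.raises(ValueError, match="never resized"):
            model.predict_vector(np.zeros((48, 48), dtype=np.uint8))

    def test_brief_training_beats_untrained(self):
        from crustavision.cli import _labelled_crops

        crops, targets = _labelled_crops(80, 64, seed=3)
        train_c, train_t = crops[:60], targets[:60]
        test_c, test_t = crops[60:], targets[60:]
        model = kp.KeypointRegressor((64, 64), pool=8, seed=0, zero_init_head=True)
        before = [kp.predict_keypoints(c, model) for c in test_c]
        mee_before = kp.mean_euclidean_error(before, test_t)
        model.fit(train_c, train_t, epochs=150, seed=0)
        after = [kp.predict_keypoints(c, model) for c in test_c]
        mee_after = kp.mean_euclidean_error(after, test_t)
        assert mee_after < mee_before

    def test_save_load_round_trip(self, tmp_path):
        model = kp.KeypointRegressor((64, 64), seed=5)
        crop = np.random.default_rng(1).integers(0, 256, (64, 64), dtype=np.uint8)
        path = tmp_path / "kp.npz"
        model.save(path)
        back = kp.KeypointRegressor.load(path, input_size=(64, 64))
        np.testing.assert_allclose(back.predict_vector(crop), model.predict_vector(crop))


class TestViaImport:
    def test_point_regions_parsed(self, tmp_path):
        regions = [
            {
                "shape_attributes": {"name": "point", "cx": 10 + i, "cy": 20 + i},
                "region_attributes": {"name": name},
            }
            for i, name in enumerate(kp.KEYPOINT_NAMES)
        ]
        payload = {
            "_via_img_metadata": {
                "img1.png-1": {"filename": "img1.png", "regions": regions}
            }
        }
        path = tmp_path / "via.json"
        path.write_text(json.dumps(payload))
        parsed = kp.import_via_annotations(path)
        assert set(parsed) == {"img1.png"}
        assert parsed["img1.png"]["crab_left"] == (10.0, 20.0)

    def test_non_point_regions_ignored(self, tmp_path):
        payload = {
            "_via_img_metadata": {
                "a.png-1": {
                    "filename": "a.png",
                    "regions": [
                        {
                            "shape_attributes": {"name": "rect", "x": 0, "y": 0},
                            "region_attributes": {"name": "crab_left"},
                        }
                    ],
                }
            }
        }
        path = tmp_path / "via.json"
        path.write_text(json.dumps(payload))
        assert kp.import_via_annotations(path) == {}


def test_export_keypoints_csv(tmp_path, rng):
    records = [
        {"contig_id": 0, "class": "crab", "keypoints": random_keypoint_set(rng)},
        {"contig_id": 1, "class": "undetected", "keypoints": None},
    ]
    path = tmp_path / "kps.csv"
    kp.export_keypoints_csv(records, path)
    text = path.read_text()
    assert "crab_left_x" in text.splitlines()[0]
    assert len(text.splitlines()) == 3
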