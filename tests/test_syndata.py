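"""Synthetic study generation, augmentation geometry, splits, label IO."""

import math

import numpy as np
import pytest

from lesiondet.boxgeom import Box
from lesiondet.syndata import (ADC, LCC, SCC, SCLC, AugmentParams,
                               CaseRegistry, SubtypeSpec, augment_samples,
                               box_to_yolo_row, generate_study,
                               kfold_partitions, full_registry, read_dataset,
                               rotate_point, select_slices, split_dataset,
                               tiny_registry, translate_point, write_dataset,
                               yolo_row_to_box)


class TestRegistry:
    def test_full_profile_expected_counts(self):
        counts = full_registry().expected_counts()
        assert counts == {ADC: 1287, SCLC: 440, LCC: 1190, SCC: 1215}

    def test_full_profile_augments_only_the_minority_class(self):
        reg = full_registry()
        assert reg.spec(SCLC).augment_factor == 2
        for c in (LCC, ADC, SCC):
            assert reg.spec(c).augment_factor == 1

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SubtypeSpec(cases=-1, slices_per_case=3)
        with pytest.raises(ValueError):
            SubtypeSpec(cases=1, slices_per_case=1, augment_factor=0)

    def test_yaml_roundtrip(self, tmp_path):
        reg = tiny_registry()
        reg.to_yaml(tmp_path / "reg.yaml")
        assert CaseRegistry.from_yaml(tmp_path / "reg.yaml") == reg

    def test_slice_selection_rule(self):
        assert select_slices(10, 3) == [0, 1, 2]
        with pytest.raises(ValueError):
            select_slices(2, 5)


class TestGeneration:
    def test_counts_follow_registry(self, tiny_samples):
        reg = tiny_registry()
        for c, expect in reg.expected_counts().items():
            assert sum(1 for s in tiny_samples if s.class_id == c) == expect

    def test_deterministic_from_seed(self):
        reg = CaseRegistry.from_dict({SCLC: SubtypeSpec(2, 2)})
        a = generate_study(reg, 64, seed=5)
        b = generate_study(reg, 64, seed=5)
        for s, t in zip(a, b):
            assert np.array_equal(s.image, t.image)
            assert s.boxes[0] == t.boxes[0]
        c = generate_study(reg, 64, seed=6)
        assert not all(np.array_equal(s.image, t.image) for s, t in zip(a, c))

    def test_boxes_valid_and_on_canvas(self, tiny_samples):
        for s in tiny_samples:
            w, h = s.canvas_size()
            for b in s.boxes:
                assert b.x2 > b.x1 and b.y2 > b.y1
                assert 0 <= b.x1 and b.x2 <= w and 0 <= b.y1 and b.y2 <= h

    def test_subtype_conditional_lesion_sizes(self, tiny_samples):
        """Small-cell lesions are systematically smaller than large-cell."""
        mean_area = {}
        for c in (SCLC, LCC):
            areas = [b.area for s in tiny_samples if s.class_id == c for b in s.boxes]
            mean_area[c] = np.mean(areas)
        assert mean_area[SCLC] < 0.5 * mean_area[LCC]

    def test_too_small_canvas_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_study(tiny_registry(), image_size=16, seed=0)


class TestPointTransforms:
    def test_quarter_turn(self):
        x, y = rotate_point((1, 0), (0, 0), math.pi / 2)
        assert (x, y) == pytest.approx((0, 1), abs=1e-12)

    def test_center_is_fixed_point(self):
        for theta in (0.3, 1.2, 4.0):
            assert rotate_point((3, 7), (3, 7), theta) == pytest.approx((3, 7))

    def test_half_turn_worked_example(self):
        assert rotate_point((2, 3), (1, 1), math.pi) == pytest.approx((0, -1), abs=1e-12)

    def test_translate_and_inverse(self):
        assert translate_point((0, 0), (3, 4)) == (3, 4)
        assert translate_point((5, 6), (0, 0)) == (5, 6)
        p = translate_point(translate_point((2.5, -1), (3, 4)), (-3, -4))
        assert p == pytest.approx((2.5, -1))

    def test_rotation_preserves_distance_from_center(self):
        center = (32.0, 32.0)
        p = (10.0, 50.0)
        d0 = math.hypot(p[0] - center[0], p[1] - center[1])
        for theta in (0.1, 0.9, 2.7):
            q = rotate_point(p, center, theta)
            assert math.hypot(q[0] - center[0], q[1] - center[1]) == pytest.approx(d0)


class TestAugmentation:
    def test_factor_one_returns_input_unchanged(self, tiny_samples):
        subset = tiny_samples[:5]
        out = augment_samples(subset, 1, seed=0)
        assert len(out) == 5 and all(a is b for a, b in zip(out, subset))

    def test_factor_doubles_counts_and_sets_provenance(self, tiny_samples):
        subset = [s for s in tiny_samples if s.class_id == SCLC][:10]
        out = augment_samples(subset, 2, seed=3)
        assert len(out) == 20
        assert sum(s.provenance == "augmented" for s in out) == 10
        assert all(s.class_id == SCLC for s in out)

    def test_identity_transform_reproduces_image_and_boxes(self, tiny_samples):
        s = tiny_samples[0]
        ident = AugmentParams(cx=32.0, cy=32.0, theta=0.0, dx=0.0, dy=0.0)
        out = augment_samples([s], 2, param_sampler=lambda rng, smp: ident, seed=0)
        aug = out[1]
        assert np.array_equal(aug.image, s.image)
        for a, b in zip(aug.boxes, s.boxes):
            assert a.as_array() == pytest.approx(b.as_array(), abs=1e-9)

    def test_augmented_boxes_stay_on_canvas(self, tiny_samples):
        subset = [s for s in tiny_samples if s.class_id == LCC][:8]
        out = augment_samples(subset, 3, seed=11)
        for s in out:
            w, h = s.canvas_size()
            for b in s.boxes:
                assert 0 <= b.x1 < b.x2 <= w and 0 <= b.y1 < b.y2 <= h

    def test_invalid_factor_rejected(self, tiny_samples):
        with pytest.raises(ValueError):
            augment_samples(tiny_samples[:1], 0)


class TestSplits:
    def _hundred_cases(self):
        reg = CaseRegistry.from_dict({SCLC: SubtypeSpec(50, 1), ADC: SubtypeSpec(50, 1)})
        return generate_study(reg, 64, seed=2)

    def test_eighty_ten_ten(self):
        train, val, test = split_dataset(self._hundred_cases(), seed=4)
        assert (len(train), len(val), len(test)) == (80, 10, 10)

    def test_partitions_disjoint_and_cover(self, tiny_samples):
        train, val, test = split_dataset(tiny_samples, seed=1)
        ids = lambda part: {(s.class_id, s.case_id, id(s)) for s in part}
        assert len(train) + len(val) + len(test) == len(tiny_samples)
        assert not (ids(train) & ids(val)) and not (ids(val) & ids(test))

    def test_case_level_no_leakage(self, tiny_samples):
        train, val, test = split_dataset(tiny_samples, seed=1)
        keys = [{(s.class_id, s.case_id) for s in p} for p in (train, val, test)]
        assert not (keys[0] & keys[1]) and not (keys[0] & keys[2]) and not (keys[1] & keys[2])

    def test_stratified_proportions_within_two_cases(self):
        samples = self._hundred_cases()
        for seed in range(5):
            train, val, test = split_dataset(samples, seed=seed)
            for c in (SCLC, ADC):
                n_val = len({s.case_id for s in val if s.class_id == c})
                assert abs(n_val - 5) <= 2
        with pytest.raises(ValueError):
            split_dataset(samples[:2], ratios=(0.5, 0.25, 0.25))

    def test_kfold_balanced_and_exhaustive(self):
        samples = self._hundred_cases()[:50]
        folds = kfold_partitions(samples, 5, seed=0)
        assert len(folds) == 5
        val_cases = []
        for train, val in folds:
            cases = {s.case_id for s in val}
            assert len(cases) == 10
            val_cases.append(cases)
            assert len(train) + len(val) == 50
        all_cases = set().union(*val_cases)
        assert len(all_cases) == 50          # every case validates exactly once
        assert kfold_partitions(samples, 5, seed=0)[0][1][0].case_id == \
            folds[0][1][0].case_id            # reproducible under the seed

    def test_kfold_validation(self):
        samples = self._hundred_cases()[:4]
        with pytest.raises(ValueError):
            kfold_partitions(samples, 1)
        with pytest.raises(ValueError):
            kfold_partitions(samples, 10)


class TestLabelIO:
    def test_corner_box_row(self):
        row = box_to_yolo_row(2, Box(0, 0, 10, 10), (100, 100))
        assert row == "2 0.05 0.05 0.1 0.1"

    def test_roundtrip_single_row(self):
        cls, box = yolo_row_to_box("3 0.5 0.25 0.2 0.1", (200, 80))
        assert cls == 3
        assert box.as_array() == pytest.approx([80.0, 16.0, 120.0, 24.0])

    def test_malformed_row_rejected(self):
        with pytest.raises(ValueError):
            yolo_row_to_box("1 0.5 0.5", (64, 64))

    def test_dataset_roundtrip(self, tmp_path, tiny_samples):
        subset = tiny_samples[:12]
        write_dataset(subset, tmp_path)
        back = read_dataset(tmp_path)
        assert len(back) == 12
        for a, b in zip(subset, back):
            assert a.class_id == b.class_id
            assert a.case_id == b.case_id
            assert a.provenance == b.provenance
            assert np.array_equal(a.image, b.image)
            for ba, bb in zip(a.boxes, b.boxes):
                assert ba.as_array() == pytest.approx(bb.as_array(), abs=1e-3)

    def test_empty_label_file_means_lesion_free(self, tmp_path, tiny_samples):
        s = tiny_samples[0]
        lesion_free = type(s)(case_id="clean", class_id=0, image=s.image,
                              boxes=[], provenance="original")
        write_dataset([lesion_free], tmp_path)
        back = read_dataset(tmp_path)
        assert back[0].boxes == []

    def test_malformed_file_error_names_file_and_line(self, tmp_path, tiny_samples):
        write_dataset(tiny_samples[:1], tmp_path)
        label = next((tmp_path / "labels").glob("*.txt"))
        label.write_text("0 0.5 0.5 0.1 0.1\n0 bad row\n")
        with pytest.raises(ValueError, match=r"\.txt:2"):
            read_dataset(tmp_path)
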