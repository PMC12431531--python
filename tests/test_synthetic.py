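"""Scene generator: determinism, separability, augmentation, dataset I/O."""

import numpy as np
import pytest

from pigstressnet.fusion import redness_index
from pigstressnet.synthetic import (Annotation, AugmentSpec, PlacementError,
                                    SceneSpec, augment, generate_scene,
                                    read_dataset, write_dataset)


class TestGeneration:
    def test_bitwise_deterministic(self):
        spec = SceneSpec(image_size=160, n_pigs=4, seed=9)
        i1, a1 = generate_scene(spec)
        i2, a2 = generate_scene(spec)
        np.testing.assert_array_equal(i1, i2)
        assert [(a.cls, a.box) for a in a1] == [(a.cls, a.box) for a in a2]

    def test_empty_scene(self):
        img, anns = generate_scene(SceneSpec(image_size=96, n_pigs=0, seed=0))
        assert img.shape == (96, 96, 3)
        assert anns == []

    def test_overcrowded_scene_raises(self):
        with pytest.raises(PlacementError):
            generate_scene(SceneSpec(image_size=96, n_pigs=60, seed=0,
                                     max_place_attempts=8))

    def test_boxes_inside_image_and_classes_valid(self):
        for seed in range(10):
            img, anns = generate_scene(SceneSpec(image_size=160, n_pigs=4,
                                                 seed=seed))
            for a in anns:
                assert 0 <= a.x1 < a.x2 <= 160
                assert 0 <= a.y1 < a.y2 <= 160
                assert 0 <= a.cls <= 4

    def test_stress_population_exceeds_threshold(self):
        # 1000 stress pigs; the rendered redness index should clear the
        # 0.05 threshold at roughly the truncated-normal tail rate
        n, n_ok = 0, 0
        seed = 0
        while n < 1000:
            img, anns = generate_scene(SceneSpec(
                image_size=160, n_pigs=4, seed=seed, pose_pool=("stress",)))
            seed += 1
            for a in anns:
                n += 1
                n_ok += redness_index(img, a.box) > 0.05
        assert n_ok / n >= 0.93

    def test_redness_separation_between_classes(self):
        stress_vals, normal_vals = [], []
        for seed in range(30):
            img, anns = generate_scene(SceneSpec(image_size=160, n_pigs=4,
                                                 seed=seed))
            for a in anns:
                (stress_vals if a.cls == 4 else normal_vals).append(
                    redness_index(img, a.box))
        # effect size > 2 SD by construction
        gap = np.mean(stress_vals) - np.mean(normal_vals)
        assert gap > 2 * np.std(normal_vals)


class TestAugment:
    def test_copy_count(self, small_scene):
        img, anns = small_scene
        out = augment(img, anns, AugmentSpec(copies_per_image=10), seed=3)
        assert len(out) == 10

    def test_corpus_expansion_710_to_7100(self):
        img = np.full((16, 16, 3), 128, dtype=np.uint8)
        ann = [Annotation(0, 2, 2, 10, 10)]
        total = sum(len(augment(img, ann, AugmentSpec(), seed=s))
                    for s in range(710))
        assert total == 7100

    def test_hflip_remaps_boxes_exactly(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        ann = [Annotation(3, 3.2, 4.0, 9.6, 12.0)]
        spec = AugmentSpec(hflip_prob=1.0, copies_per_image=1,
                           brightness_delta=0.0, contrast_delta=0.0)
        (img2, anns2), = augment(img, ann, spec, seed=0)
        a = anns2[0]
        assert (a.x1, a.x2) == (32 - 9.6, 32 - 3.2)
        assert (a.y1, a.y2) == (4.0, 12.0)
        # cx = 0.2 -> 0.8 under reflection
        ann_c = [Annotation(0, 0.2 * 32 - 2, 0, 0.2 * 32 + 2, 8)]
        (_, flipped), = augment(img, ann_c, spec, seed=0)
        cx = (flipped[0].x1 + flipped[0].x2) / 2 / 32
        assert cx == pytest.approx(0.8)

    def test_occlusion_patch_area_bounded(self):
        # photometric jitter off, so the only changed pixels are the patch
        img = np.full((64, 64, 3), 128, dtype=np.uint8)
        spec = AugmentSpec(copies_per_image=1, hflip_prob=0.0,
                           brightness_delta=0.0, contrast_delta=0.0)
        worst = 0
        for seed in range(10_000):
            (out, _), = augment(img, [], spec, seed=seed)
            changed = int(np.any(out != img, axis=-1).sum())
            worst = max(worst, changed)
        assert 0 < worst <= 0.15 * 64 * 64

    def test_augmented_boxes_stay_normalized_positive(self, small_scene):
        img, anns = small_scene
        for img2, anns2 in augment(img, anns, AugmentSpec(), seed=5):
            for a in anns2:
                assert 0 <= a.x1 < a.x2 <= img.shape[1]
                assert 0 <= a.y1 < a.y2 <= img.shape[0]


class TestDatasetIO:
    def test_label_line_for_centered_half_size_lying_pig(self):
        a = Annotation(3, 40, 40, 120, 120)
        assert a.yolo_line(160) == "3 0.500000 0.500000 0.500000 0.500000"

    def test_round_trip(self, tmp_path):
        scenes = [generate_scene(SceneSpec(image_size=128, n_pigs=3, seed=s))
                  for s in range(5)]
        yaml_path = write_dataset(scenes, str(tmp_path), split=0.8)
        train = read_dataset(yaml_path, "train")
        val = read_dataset(yaml_path, "val")
        assert len(train) == 4 and len(val) == 1
        img0, anns0 = train[0]
        np.testing.assert_array_equal(img0, scenes[0][0])
        for orig, back in zip(scenes[0][1], anns0):
            assert orig.cls == back.cls
            np.testing.assert_allclose(back.box, orig.box, atol=128 * 2e-6)

    def test_class_name_order_in_yaml(self, tmp_path):
        import yaml as _yaml
        scenes = [generate_scene(SceneSpec(image_size=96, n_pigs=0, seed=0))]
        path = write_dataset(scenes, str(tmp_path))
        cfg = _yaml.safe_load(open(path))
        assert cfg["names"] == {0: "stand", 1: "eat", 2: "sit",
                                3: "lying", 4: "stress"}
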