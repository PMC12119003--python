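"""Scene generator statistics, split arithmetic, label I/O, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lesiondet.data_synth import (
    Annotation,
    DatasetManifest,
    LabelFormatError,
    SceneSpec,
    augment,
    build_dataset,
    generate_scene,
    read_yolo_labels,
    split_dataset,
    write_yolo_labels,
)

SMALL = SceneSpec(image_hw=(160, 160), area_range=(200.0, 8000.0), num_classes=15)


class TestGenerateScene:
    def test_fixed_seed_reproduces_bytes(self):
        img_a, ann_a = generate_scene(SMALL, seed=123)
        img_b, ann_b = generate_scene(SMALL, seed=123)
        assert img_a.tobytes() == img_b.tobytes()
        assert ann_a == ann_b
        img_c, _ = generate_scene(SMALL, seed=124)
        assert img_c.tobytes() != img_a.tobytes()

    def test_box_areas_respect_configured_range(self):
        spec = SceneSpec(image_hw=(160, 160), area_range=(200.0, 8000.0),
                         num_classes=15, oversize_tail=0.0)
        h, w = spec.image_hw
        areas = []
        for seed in range(60):
            _, anns = generate_scene(spec, seed)
            areas += [a.w * w * a.h * h for a in anns]
        assert areas and all(200.0 - 1e-6 <= ar <= 8000.0 + 1e-6 for ar in areas)

    def test_oversize_tail_produces_larger_boxes(self):
        spec = SceneSpec(image_hw=(256, 256), area_range=(200.0, 8000.0),
                         num_classes=15, oversize_tail=1.0)
        _, anns = generate_scene(spec, seed=5)
        assert anns and all(a.w * 256 * a.h * 256 > 8000.0 for a in anns)

    def test_mean_object_count_matches_poisson_rate(self):
        spec = SceneSpec(image_hw=(96, 96), area_range=(100.0, 1500.0),
                         num_classes=15, mean_objects=2.0)
        counts = [len(generate_scene(spec, s)[1]) for s in range(1000)]
        se = np.sqrt(2.0 / len(counts))
        assert abs(np.mean(counts) - 2.0) < 3 * se

    @pytest.mark.parametrize("seed", range(25))
    def test_annotations_always_valid(self, seed):
        _, anns = generate_scene(SMALL, seed)
        for a in anns:
            a.validate(SMALL.num_classes)

    def test_infeasible_area_range_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(image_hw=(32, 32), area_range=(200.0, 8000.0))


class TestSplit:
    def test_published_corpus_size_split(self):
        sizes, _ = split_dataset(5841, (0.7, 0.2, 0.1), seed=0)
        assert sizes == (4088, 1168, 585)

    @pytest.mark.parametrize("n,expected", [(10, (7, 2, 1)), (3, (2, 0, 1)), (0, (0, 0, 0))])
    def test_floor_floor_remainder_rule(self, n, expected):
        sizes, _ = split_dataset(n)
        assert sizes == expected

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 500), st.integers(0, 10))
    def test_assignment_partitions_everything(self, n, seed):
        sizes, tags = split_dataset(n, seed=seed)
        assert sum(sizes) == n == len(tags)
        assert (tags == "train").sum() == sizes[0]
        assert (tags == "val").sum() == sizes[1]
        assert (tags == "test").sum() == sizes[2]

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(10, (0.5, 0.2, 0.1))


class TestLabelIO:
    def test_single_line_parse(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("3 0.5 0.5 0.2 0.1\n")
        assert read_yolo_labels(p) == [Annotation(3, 0.5, 0.5, 0.2, 0.1)]

    def test_round_trip_identity(self, tmp_path):
        anns = [Annotation(0, 0.25, 0.75, 0.5, 0.25), Annotation(4, 0.5, 0.5, 0.125, 0.0625)]
        p = tmp_path / "b.txt"
        write_yolo_labels(p, anns)
        assert read_yolo_labels(p, num_classes=5) == anns

    def test_out_of_range_center_reported_with_line_number(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("0 0.5 0.5 0.2 0.1\n3 1.5 0.5 0.2 0.1\nbogus line here oops x\n")
        with pytest.raises(LabelFormatError) as exc:
            read_yolo_labels(p)
        lines = [ln for ln, _ in exc.value.offenders]
        assert lines == [2, 3]

    def test_unknown_class_rejected(self, tmp_path):
        p = tmp_path / "d.txt"
        p.write_text("9 0.5 0.5 0.2 0.1\n")
        with pytest.raises(LabelFormatError):
            read_yolo_labels(p, num_classes=5)


@pytest.fixture
def scene():
    return generate_scene(SMALL, seed=3)


class TestAugment:
    def test_hflip_mirrors_centers_only(self, scene):
        img, anns = scene
        out, flipped = augment(img, anns, "hflip")
        assert np.array_equal(out, img[:, ::-1])
        for a, f in zip(anns, flipped):
            assert f.cx == pytest.approx(1.0 - a.cx)
            assert (f.cy, f.w, f.h) == (a.cy, a.w, a.h)

    def test_hflip_is_an_involution(self, scene):
        img, anns = scene
        img2, anns2 = augment(*augment(img, anns, "hflip"), "hflip")
        assert np.array_equal(img2, img)
        for a, b in zip(anns, anns2):
            assert b.cx == pytest.approx(a.cx) and b.cy == a.cy

    @pytest.mark.parametrize("angle", [0.0, 360.0])
    def test_zero_rotation_is_identity(self, scene, angle):
        img, anns = scene
        out, anns2 = augment(img, anns, "rotate", angle=angle)
        assert np.array_equal(out, img)
        assert anns2 == anns

    def test_rotation_preserves_count_for_small_angles(self, scene):
        img, anns = scene
        _, anns2 = augment(img, anns, "rotate", angle=5.0)
        assert len(anns2) == len(anns)

    def test_crop_geometry_and_drop_rule(self, scene):
        img, anns = scene
        out, anns2 = augment(img, anns, "crop", crop_box=(0, 0, 120, 120))
        assert out.shape[:2] == (120, 120)
        for a in anns2:
            a.validate(SMALL.num_classes)
        # an off-image crop of a fully annotated scene can only drop boxes
        assert len(anns2) <= len(anns)

    def test_crop_larger_than_image_rejected(self, scene):
        img, anns = scene
        with pytest.raises(ValueError):
            augment(img, anns, "crop", crop_box=(0, 0, 200, 200))

    @pytest.mark.parametrize("op", ["brightness", "contrast"])
    def test_photometric_ops_leave_annotations_unchanged(self, scene, op):
        img, anns = scene
        out, anns2 = augment(img, anns, op, factor=1.3)
        assert anns2 == anns
        assert out.shape == img.shape and out.dtype == img.dtype

    def test_unknown_op_rejected(self, scene):
        with pytest.raises(ValueError):
            augment(*scene, "solarize")


class TestDatasetLayout:
    def test_build_and_reload_manifest(self, tiny_dataset):
        reloaded = DatasetManifest.from_dir(tiny_dataset.root)
        assert reloaded.names == tiny_dataset.names
        assert len(reloaded.records) == len(tiny_dataset.records)
        for tag in ("train", "val", "test"):
            assert len(reloaded.split(tag)) == len(tiny_dataset.split(tag))
        got = {a for _, anns, _ in reloaded.records for a in anns}
        want = {a for _, anns, _ in tiny_dataset.records for a in anns}
        # label round trip through files preserves boxes to written precision
        assert len(got) == len(want)
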