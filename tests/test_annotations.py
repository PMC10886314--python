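"""COCO JSON, label masks, YOLO text: parsing, validation, round trips."""
import json

import numpy as np
import pytest

from sonotriage.annotations import (
    Annotation,
    AnnotationError,
    AnnotationSet,
    Category,
    ImageInfo,
    annotations_to_label_mask,
    read_coco,
    read_yolo_seg,
    resize_mask,
    write_coco,
    write_yolo_seg,
)
from sonotriage.polygons import polygon_to_mask, trace_binary_regions


def _minimal_set() -> AnnotationSet:
    return AnnotationSet(
        images=[ImageInfo(1, "a.png", 32, 32)],
        categories=[Category(4, "shrapnel")],
        annotations=[
            Annotation(1, 4, ((4.0, 4.0), (12.0, 4.0), (12.0, 12.0), (4.0, 12.0)))
        ],
    )


class TestCocoIO:
    def test_minimal_file_reads(self, tmp_path):
        doc = {
            "images": [{"id": 1, "file_name": "a.png", "width": 32, "height": 32}],
            "categories": [{"id": 4, "name": "shrapnel"}],
            "annotations": [
                {"id": 1, "image_id": 1, "category_id": 4,
                 "segmentation": [[4, 4, 12, 4, 12, 12, 4, 12]]}
            ],
        }
        path = tmp_path / "c.json"
        path.write_text(json.dumps(doc))
        annset = read_coco(path)
        assert len(annset.images) == 1 and len(annset.annotations) == 1
        assert annset.annotations[0].polygon[1] == (12.0, 4.0)

    def test_dangling_image_id_rejected(self, tmp_path):
        doc = {
            "images": [{"id": 1, "file_name": "a.png", "width": 32, "height": 32}],
            "categories": [{"id": 4, "name": "shrapnel"}],
            "annotations": [
                {"id": 1, "image_id": 99, "category_id": 4,
                 "segmentation": [[4, 4, 12, 4, 12, 12]]}
            ],
        }
        path = tmp_path / "c.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(AnnotationError, match="image_id 99"):
            read_coco(path)

    def test_rle_segmentation_rejected(self, tmp_path):
        doc = {
            "images": [{"id": 1, "file_name": "a.png", "width": 32, "height": 32}],
            "categories": [{"id": 4, "name": "shrapnel"}],
            "annotations": [
                {"id": 1, "image_id": 1, "category_id": 4,
                 "segmentation": {"counts": [0, 10], "size": [32, 32]}}
            ],
        }
        path = tmp_path / "c.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(AnnotationError, match="RLE"):
            read_coco(path)

    def test_missing_key_rejected(self, tmp_path):
        path = tmp_path / "c.json"
        path.write_text(json.dumps({"images": [], "annotations": []}))
        with pytest.raises(AnnotationError, match="categories"):
            read_coco(path)

    def test_round_trip_random_sets(self, tmp_path, rng):
        for trial in range(20):
            n_img = int(rng.integers(1, 4))
            images = [ImageInfo(i + 1, f"im{i}.png", 64, 64) for i in range(n_img)]
            cats = [Category(1, "vein"), Category(4, "shrapnel")]
            anns = []
            for _ in range(int(rng.integers(0, 5))):
                pts = rng.uniform(1, 63, size=(int(rng.integers(3, 8)), 2))
                anns.append(
                    Annotation(
                        int(rng.choice([im.id for im in images])),
                        int(rng.choice([1, 4])),
                        tuple(map(tuple, pts.round(6).tolist())),
                    )
                )
            annset = AnnotationSet(images, cats, anns)
            path = tmp_path / f"rt{trial}.json"
            write_coco(annset, path)
            assert read_coco(path) == annset

    def test_empty_set_round_trips(self, tmp_path):
        annset = AnnotationSet()
        path = tmp_path / "empty.json"
        write_coco(annset, path)
        assert read_coco(path) == annset

    def test_coordinates_preserved_to_high_precision(self, tmp_path):
        poly = ((1.1234567, 2.7654321), (10.0000001, 2.0), (5.5, 9.999999))
        annset = AnnotationSet(
            [ImageInfo(1, "a.png", 32, 32)], [Category(1, "vein")], [Annotation(1, 1, poly)]
        )
        path = tmp_path / "p.json"
        write_coco(annset, path)
        back = read_coco(path).annotations[0].polygon
        assert back == poly  # JSON floats round-trip exactly


class TestMaskConversion:
    def test_square_polygon_center_inside_count(self):
        annset = AnnotationSet(
            [ImageInfo(1, "a.png", 8, 8)],
            [Category(1, "vein")],
            [Annotation(1, 1, ((0.0, 0.0), (4.0, 0.0), (4.0, 4.0), (0.0, 4.0)))],
        )
        mask = annotations_to_label_mask(annset, 1, {"background": 0, "vein": 1})
        assert (mask == 1).sum() == 16
        assert (mask[:4, :4] == 1).all()

    def test_image_without_annotations_is_background(self):
        annset = AnnotationSet([ImageInfo(1, "a.png", 8, 8)], [], [])
        mask = annotations_to_label_mask(annset, 1, {"background": 0})
        assert (mask == 0).all()

    def test_overlap_resolved_by_higher_label(self):
        square = ((2.0, 2.0), (8.0, 2.0), (8.0, 8.0), (2.0, 8.0))
        annset = AnnotationSet(
            [ImageInfo(1, "a.png", 12, 12)],
            [Category(1, "vein"), Category(4, "shrapnel")],
            [Annotation(1, 1, square), Annotation(1, 4, square)],
        )
        table = {"background": 0, "vein": 1, "shrapnel": 4}
        mask = annotations_to_label_mask(annset, 1, table)
        assert (mask[3:7, 3:7] == 4).all()

    def test_unknown_category_raises_with_name(self):
        annset = _minimal_set()
        with pytest.raises(AnnotationError, match="shrapnel"):
            annotations_to_label_mask(annset, 1, {"background": 0, "vein": 1})


class TestResizeMask:
    def test_identity(self, rng):
        mask = rng.integers(0, 5, size=(32, 32)).astype(np.uint8)
        assert np.array_equal(resize_mask(mask, 32), mask)

    def test_downscale_index_mapping(self):
        mask = np.zeros((512, 512), dtype=np.uint8)
        mask[100:102, 100:102] = 3
        out = resize_mask(mask, 256)
        # centre of out pixel 50 maps to input row floor(50.5 * 2) = 101
        assert out[50, 50] == 3

    def test_no_new_labels(self, rng):
        mask = (rng.random((48, 48)) < 0.2).astype(np.uint8) * 3
        for size in (17, 48, 96, 200):
            out = resize_mask(mask, size)
            assert set(np.unique(out)) <= set(np.unique(mask))

    def test_idempotent_at_target_size(self, rng):
        mask = rng.integers(0, 5, size=(64, 64)).astype(np.uint8)
        once = resize_mask(mask, 40)
        assert np.array_equal(resize_mask(once, 40), once)

    def test_bad_size_raises(self):
        with pytest.raises(ValueError):
            resize_mask(np.zeros((4, 4), dtype=np.uint8), 0)


class TestYoloText:
    def test_normalized_coordinates_in_unit_interval(self, tmp_path):
        annset = AnnotationSet(
            [ImageInfo(1, "a.png", 512, 512)],
            [Category(4, "shrapnel")],
            [Annotation(1, 4, ((10.0, 20.0), (400.0, 20.0), (400.0, 300.0), (10.0, 300.0)))],
        )
        (path,) = write_yolo_seg(annset, tmp_path / "y")
        fields = path.read_text().split()
        assert fields[0] == "0"
        coords = list(map(float, fields[1:]))
        assert len(coords) == 8 and all(0.0 <= v <= 1.0 for v in coords)

    def test_round_trip_within_half_pixel(self, tmp_path, dataset96):
        _, annset = dataset96
        write_yolo_seg(annset, tmp_path / "y")
        back = read_yolo_seg(tmp_path / "y", annset.images, annset.categories)
        assert len(back.annotations) == len(annset.annotations)
        for a, b in zip(annset.annotations, back.annotations):
            assert a.image_id == b.image_id and a.category_id == b.category_id
            for (x1, y1), (x2, y2) in zip(a.polygon, b.polygon):
                assert abs(x1 - x2) < 0.5 and abs(y1 - y2) < 0.5

    def test_empty_image_gives_empty_file(self, tmp_path):
        annset = AnnotationSet([ImageInfo(1, "a.png", 64, 64)], [Category(1, "vein")], [])
        (path,) = write_yolo_seg(annset, tmp_path / "y")
        assert path.read_text() == ""

    def test_malformed_line_cites_location(self, tmp_path):
        d = tmp_path / "y"
        d.mkdir()
        (d / "a.txt").write_text("0 0.1 0.2 0.3\n")
        with pytest.raises(AnnotationError, match="a.txt:1"):
            read_yolo_seg(d, [ImageInfo(1, "a.png", 64, 64)], [Category(1, "vein")])


class TestPolygonPrimitives:
    def test_trace_then_rasterize_is_identity_on_random_blobs(self, rng):
        from scipy import ndimage

        for _ in range(10):
            blob = ndimage.binary_dilation(
                rng.random((24, 24)) < 0.04, iterations=int(rng.integers(1, 4))
            )
            loops = trace_binary_regions(blob)
            rebuilt = np.zeros_like(blob)
            for loop in loops:
                # XOR composes outer and hole loops under even-odd parity
                rebuilt ^= polygon_to_mask(loop, blob.shape)
            assert np.array_equal(rebuilt, blob)

    def test_single_pixel_traces_to_unit_square(self):
        blob = np.zeros((4, 4), dtype=bool)
        blob[2, 1] = True
        (loop,) = trace_binary_regions(blob)
        assert sorted(map(tuple, loop.tolist())) == [(1, 2), (1, 3), (2, 2), (2, 3)]
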