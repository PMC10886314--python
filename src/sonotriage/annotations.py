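"""COCO polygon annotations, label masks, and YOLO segmentation text files.

Supports the three label representations used when preparing ultrasound
phantom images for segmentation training: COCO-dialect JSON with polygon
segmentations, one-channel integer label masks (PNG), and per-image YOLO
segmentation text files with polygon vertices normalized to [0, 1].

Coordinate convention: 0-based, x = column, y = row, origin top-left,
polygon vertices in continuous pixel-corner coordinates.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .polygons import polygon_to_mask

__all__ = [
    "AnnotationError",
    "ImageInfo",
    "Category",
    "Annotation",
    "AnnotationSet",
    "read_coco",
    "write_coco",
    "annotations_to_label_mask",
    "resize_mask",
    "write_yolo_seg",
    "read_yolo_seg",
    "read_mask_png",
    "write_mask_png",
]


class AnnotationError(ValueError):
    """Structured validation failure naming the offending record."""


@dataclass(frozen=True)
class ImageInfo:
    id: int
    file_name: str
    width: int
    height: int


@dataclass(frozen=True)
class Category:
    id: int
    name: str


@dataclass(frozen=True)
class Annotation:
    image_id: int
    category_id: int
    polygon: tuple[tuple[float, float], ...]


@dataclass
class AnnotationSet:
    """In-memory model of a COCO-style polygon annotation file."""

    images: list[ImageInfo] = field(default_factory=list)
    categories: list[Category] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)

    def validate(self) -> None:
        image_ids = {im.id for im in self.images}
        if len(image_ids) != len(self.images):
            raise AnnotationError("duplicate image ids")
        cat_ids = {c.id for c in self.categories}
        if len(cat_ids) != len(self.categories):
            raise AnnotationError("duplicate category ids")
        dims = {im.id: (im.width, im.height) for im in self.images}
        for i, ann in enumerate(self.annotations):
            if ann.image_id not in image_ids:
                raise AnnotationError(
                    f"annotation {i} references missing image_id {ann.image_id}"
                )
            if ann.category_id not in cat_ids:
                raise AnnotationError(
                    f"annotation {i} references missing category_id {ann.category_id}"
                )
            if len(ann.polygon) < 3:
                raise AnnotationError(f"annotation {i}: polygon has < 3 vertices")
            w, h = dims[ann.image_id]
            for x, y in ann.polygon:
                if not (0.0 <= x <= w and 0.0 <= y <= h):
                    raise AnnotationError(
                        f"annotation {i}: vertex ({x}, {y}) outside image bounds "
                        f"{w}x{h}"
                    )

    def image_by_id(self, image_id: int) -> ImageInfo:
        for im in self.images:
            if im.id == image_id:
                return im
        raise AnnotationError(f"unknown image_id {image_id}")

    def for_image(self, image_id: int) -> list[Annotation]:
        return [a for a in self.annotations if a.image_id == image_id]


def read_coco(path: str | Path) -> AnnotationSet:
    """Read a COCO-dialect JSON file with polygon segmentations.

    RLE-encoded segmentations are rejected — only the polygon dialect is
    supported.  Structural problems raise :class:`AnnotationError` naming
    the offending record.
    """
    with open(path) as fh:
        raw = json.load(fh)
    for key in ("images", "annotations", "categories"):
        if key not in raw:
            raise AnnotationError(f"missing required COCO key: {key!r}")
    try:
        images = [
            ImageInfo(int(im["id"]), str(im["file_name"]), int(im["width"]), int(im["height"]))
            for im in raw["images"]
        ]
        categories = [Category(int(c["id"]), str(c["name"])) for c in raw["categories"]]
    except KeyError as exc:  # pragma: no cover - message path
        raise AnnotationError(f"record missing required key {exc}") from exc
    annotations = []
    for i, ann in enumerate(raw["annotations"]):
        seg = ann.get("segmentation")
        if isinstance(seg, dict) or (
            isinstance(seg, list) and seg and not isinstance(seg[0], list)
        ):
            raise AnnotationError(
                f"annotation {i}: RLE or non-polygon segmentation is not supported"
            )
        if not seg:
            raise AnnotationError(f"annotation {i}: empty segmentation")
        if len(seg) != 1:
            raise AnnotationError(
                f"annotation {i}: multi-polygon segmentations are not supported"
            )
        flat = seg[0]
        if len(flat) < 6 or len(flat) % 2 != 0:
            raise AnnotationError(f"annotation {i}: degenerate polygon {flat!r}")
        poly = tuple(zip(map(float, flat[0::2]), map(float, flat[1::2])))
        annotations.append(
            Annotation(int(ann["image_id"]), int(ann["category_id"]), poly)
        )
    annset = AnnotationSet(images, categories, annotations)
    annset.validate()
    return annset


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def write_coco(annset: AnnotationSet, path: str | Path) -> None:
    """Write COCO-dialect JSON that :func:`read_coco` reads back equal.

    Vertex coordinates are serialized as full-precision JSON floats.
    """
    annset.validate()
    anns = []
    for i, a in enumerate(annset.annotations):
        poly = np.asarray(a.polygon, dtype=float)
        xs, ys = poly[:, 0], poly[:, 1]
        anns.append(
            {
                "id": i + 1,
                "image_id": a.image_id,
                "category_id": a.category_id,
                "segmentation": [[float(v) for xy in a.polygon for v in xy]],
                "bbox": [
                    float(xs.min()),
                    float(ys.min()),
                    float(xs.max() - xs.min()),
                    float(ys.max() - ys.min()),
                ],
                "area": _shoelace_area(poly),
                "iscrowd": 0,
            }
        )
    doc = {
        "images": [
            {"id": im.id, "file_name": im.file_name, "width": im.width, "height": im.height}
            for im in annset.images
        ],
        "categories": [{"id": c.id, "name": c.name} for c in annset.categories],
        "annotations": anns,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def annotations_to_label_mask(
    annset: AnnotationSet,
    image_id: int,
    class_table: dict[str, int],
    out_size: int | None = None,
) -> np.ndarray:
    """Rasterize one image's polygon annotations into an integer label mask.

    Polygons are rasterized pixel-centre-inside at the image's native size;
    overlaps resolve by class priority (higher integer label wins); the result
    is then optionally resized (nearest neighbour) to ``out_size``.
    """
    im = annset.image_by_id(image_id)
    cat_names = {c.id: c.name for c in annset.categories}
    mask = np.zeros((im.height, im.width), dtype=np.uint8)
    pairs = []
    for ann in annset.for_image(image_id):
        name = cat_names[ann.category_id]
        if name not in class_table:
            raise AnnotationError(f"category {name!r} not present in class table")
        pairs.append((class_table[name], np.asarray(ann.polygon, dtype=float)))
    for label, poly in sorted(pairs, key=lambda t: t[0]):
        mask[polygon_to_mask(poly, mask.shape)] = label
    if out_size is not None:
        mask = resize_mask(mask, out_size)
    return mask


def resize_mask(mask: np.ndarray, out_size: int | tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a categorical label mask.

    Each output pixel takes the label of the input pixel containing its
    centre, so no new labels are ever invented and a same-size call is the
    identity.
    """
    if isinstance(out_size, int):
        out_h = out_w = out_size
    else:
        out_h, out_w = out_size
    if out_h < 1 or out_w < 1:
        raise ValueError("out_size must be >= 1")
    in_h, in_w = mask.shape
    if (out_h, out_w) == (in_h, in_w):
        return mask.copy()
    rows = np.minimum((np.arange(out_h) + 0.5) * in_h / out_h, in_h - 1).astype(int)
    cols = np.minimum((np.arange(out_w) + 0.5) * in_w / out_w, in_w - 1).astype(int)
    return mask[np.ix_(rows, cols)]


def _txt_name(file_name: str) -> str:
    return Path(file_name).stem + ".txt"


def write_yolo_seg(annset: AnnotationSet, directory: str | Path) -> list[Path]:
    """Write one YOLO segmentation text file per image.

    Each line is ``class_index x1 y1 x2 y2 ...`` with the class index being
    the position of the category in ``annset.categories`` (sorted by id) and
    vertices normalized to [0, 1] by the image width/height (6 decimals).
    Images with no annotations yield an empty file.
    """
    annset.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cat_index = {c.id: i for i, c in enumerate(sorted(annset.categories, key=lambda c: c.id))}
    written = []
    for im in annset.images:
        lines = []
        for ann in annset.for_image(im.id):
            coords = []
            for x, y in ann.polygon:
                coords.append(f"{x / im.width:.6f}")
                coords.append(f"{y / im.height:.6f}")
            lines.append(" ".join([str(cat_index[ann.category_id])] + coords))
        out = directory / _txt_name(im.file_name)
        out.write_text("\n".join(lines) + ("\n" if lines else ""))
        written.append(out)
    return written


def read_yolo_seg(
    directory: str | Path,
    images: list[ImageInfo],
    categories: list[Category],
) -> AnnotationSet:
    """Read YOLO segmentation text files back into an :class:`AnnotationSet`.

    ``images`` supplies the image table (file names and pixel dimensions,
    required to undo coordinate normalization); ``categories`` maps class
    indices (position in the id-sorted category list) back to category ids.
    Inverts :func:`write_yolo_seg` up to the 1e-6 coordinate precision.
    """
    directory = Path(directory)
    sorted_cats = sorted(categories, key=lambda c: c.id)
    annotations = []
    for im in images:
        path = directory / _txt_name(im.file_name)
        if not path.exists():
            raise AnnotationError(f"missing YOLO file {path}")
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 7 or (len(fields) - 1) % 2 != 0:
                raise AnnotationError(f"{path}:{lineno}: malformed segmentation line")
            try:
                idx = int(fields[0])
                vals = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed number") from exc
            if not 0 <= idx < len(sorted_cats):
                raise AnnotationError(f"{path}:{lineno}: class index {idx} out of range")
            poly = tuple(
                (x * im.width, y * im.height) for x, y in zip(vals[0::2], vals[1::2])
            )
            annotations.append(Annotation(im.id, sorted_cats[idx].id, poly))
    return AnnotationSet(list(images), list(sorted_cats), annotations)


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a single-channel 8-bit PNG label mask."""
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise AnnotationError(f"{path}: expected single-channel mask PNG")
    return arr.astype(np.uint8)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask as a single-channel 8-bit PNG."""
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)
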