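"""Synthetic ultrasound-phantom frames with exactly known ground truth.

Emulates the geometry of a gelatin tissue phantom used for foreign-body
segmentation studies: a speckle-textured tissue background, a neurovascular
bundle (vein, artery, nerve — three roughly circular channels grouped
together), and a thin bright rod of shrapnel placed at a controlled distance
from the bundle.  Rendering is geometric (piecewise-constant intensities
plus multiplicative speckle), not an acoustic simulation: no shadowing,
reverberation, or beam effects.

Every sample carries its parametric scene geometry, so the true continuous
minimum distance from the shrapnel to each neurovascular feature is known
independently of any mask-level measurement.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from ._geometry import Ellipse, RotRect, ellipse_rect_distance
from .polygons import trace_binary_regions
from .annotations import Annotation, AnnotationSet, Category, ImageInfo

__all__ = [
    "PhantomSpec",
    "SceneGeometry",
    "PhantomSample",
    "InfeasibleSpecError",
    "generate_scene",
    "rasterize_mask",
    "render_image",
    "perturb_mask",
    "generate_dataset",
    "dataset_annotations",
    "DEFAULT_CLASS_TABLE",
]

DEFAULT_CLASS_TABLE = {
    "background": 0,
    "vein": 1,
    "artery": 2,
    "nerve": 3,
    "shrapnel": 4,
}

_MAX_ATTEMPTS = 1000


class InfeasibleSpecError(RuntimeError):
    """Scene placement failed within the rejection-sampling attempt budget."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom image family.

    Lengths are in pixels.  The default shrapnel dimensions mirror a 2 mm
    diameter brass rod cut to five lengths between 0.2 and 1.0 cm at a
    1 px = 1 mm scale; vessels are biopsy-punch-like channels grouped into
    a bundle.  ``speckle_strength`` is the coefficient of variation of the
    multiplicative (unit-mean) speckle.
    """

    image_size: int = 256
    class_table: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_TABLE))
    feature_counts: dict[str, int] = field(
        default_factory=lambda: {"vein": 1, "artery": 1, "nerve": 1, "shrapnel": 1}
    )
    vessel_radius_range: tuple[float, float] = (6.0, 12.0)
    shrapnel_length_set: tuple[float, ...] = (10.0, 8.0, 6.0, 4.0, 2.0)
    shrapnel_width: float = 2.0
    bundle_spread: float = 28.0
    shrapnel_distance_range: tuple[float, float] = (1.0, 30.0)
    intensity_table: dict[str, float] = field(
        default_factory=lambda: {
            "background": 100.0,
            "vein": 30.0,
            "artery": 45.0,
            "nerve": 160.0,
            "shrapnel": 220.0,
        }
    )
    speckle_strength: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        labels = list(self.class_table.values())
        if self.class_table.get("background", None) != 0:
            raise ValueError("class table must map 'background' to 0")
        if len(set(labels)) != len(labels) or any(v < 0 for v in labels):
            raise ValueError("class labels must be distinct non-negative integers")
        if self.shrapnel_width < 1:
            raise ValueError("shrapnel_width must be >= 1 pixel")
        lim = self.image_size
        if max(self.shrapnel_length_set) >= lim or 2 * self.vessel_radius_range[1] >= lim:
            raise ValueError("geometry ranges must fit inside the image")

    @property
    def feature_classes(self) -> list[str]:
        return [n for n in self.class_table if n not in ("background", "shrapnel")]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SceneGeometry:
    """Parametric ground truth of one frame.

    ``primitives`` maps class name to its list of continuous primitives
    (ellipses for vessels/nerve, rotated rectangles for shrapnel);
    ``true_min_distances`` maps each feature class present to the continuous
    boundary-to-boundary distance from the shrapnel to that class (minimum
    over primitives), in pixels.
    """

    image_size: int
    primitives: dict[str, list]
    true_min_distances: dict[str, float]

    @property
    def true_triage_score(self) -> float | None:
        if not self.true_min_distances:
            return None
        return min(self.true_min_distances.values())


@dataclass
class PhantomSample:
    sample_id: str
    image: np.ndarray  # uint8 grayscale
    mask: np.ndarray  # uint8 labels
    scene: SceneGeometry


def _place_vessels(spec: PhantomSpec, rng: np.random.Generator) -> dict[str, list[Ellipse]]:
    size = spec.image_size
    margin = spec.vessel_radius_range[1] + 2.0
    lo, hi = margin + spec.bundle_spread, size - margin - spec.bundle_spread
    if lo >= hi:
        raise InfeasibleSpecError("bundle does not fit inside the frame")
    bcx, bcy = rng.uniform(lo, hi, size=2)
    placed: list[Ellipse] = []
    out: dict[str, list[Ellipse]] = {}
    for name in spec.feature_classes:
        out[name] = []
        for _ in range(spec.feature_counts.get(name, 0)):
            for _attempt in range(_MAX_ATTEMPTS):
                r = rng.uniform(*spec.vessel_radius_range)
                ell = Ellipse(
                    cx=bcx + rng.uniform(-spec.bundle_spread, spec.bundle_spread),
                    cy=bcy + rng.uniform(-spec.bundle_spread, spec.bundle_spread),
                    a=r,
                    b=r * rng.uniform(0.75, 1.0),
                    angle=rng.uniform(0.0, np.pi),
                )
                inside = (
                    ell.cx - margin >= 0
                    and ell.cy - margin >= 0
                    and ell.cx + margin <= size
                    and ell.cy + margin <= size
                )
                clear = all(
                    np.hypot(ell.cx - o.cx, ell.cy - o.cy)
                    > ell.bbox_radius() + o.bbox_radius() + 1.0
                    for o in placed
                )
                if inside and clear:
                    placed.append(ell)
                    out[name].append(ell)
                    break
            else:
                raise InfeasibleSpecError(
                    f"could not place {name} after {_MAX_ATTEMPTS} attempts"
                )
    return out


def generate_scene(spec: PhantomSpec, rng: np.random.Generator) -> SceneGeometry:
    """Sample one scene: bundle placement, then rejection-sampled shrapnel pose.

    The shrapnel pose is re-drawn until its continuous boundary distance to
    the nearest feature falls within ``spec.shrapnel_distance_range``; failure
    within the attempt budget raises :class:`InfeasibleSpecError`.
    """
    vessels = _place_vessels(spec, rng)
    primitives: dict[str, list] = {k: list(v) for k, v in vessels.items()}
    true_min: dict[str, float] = {}
    n_shrapnel = spec.feature_counts.get("shrapnel", 0)
    rods: list[RotRect] = []
    all_ellipses = [e for group in vessels.values() for e in group]
    size = spec.image_size
    d_lo, d_hi = spec.shrapnel_distance_range
    for _ in range(n_shrapnel):
        for _attempt in range(_MAX_ATTEMPTS):
            length = float(rng.choice(np.asarray(spec.shrapnel_length_set)))
            half = (length + spec.shrapnel_width) / 2.0 + 1.0
            rod = RotRect(
                cx=rng.uniform(half, size - half),
                cy=rng.uniform(half, size - half),
                length=length,
                width=spec.shrapnel_width,
                angle=rng.uniform(0.0, np.pi),
            )
            corners = rod.corners()
            if corners.min() < 1.0 or corners.max() > size - 1.0:
                continue
            if all_ellipses:
                dists = [ellipse_rect_distance(e, rod) for e in all_ellipses]
                if not (d_lo <= min(dists) <= d_hi):
                    continue
            if rods and any(
                np.hypot(rod.cx - r.cx, rod.cy - r.cy) < (rod.length + r.length) / 2 + 2
                for r in rods
            ):
                continue
            rods.append(rod)
            break
        else:
            raise InfeasibleSpecError(
                f"could not place shrapnel after {_MAX_ATTEMPTS} attempts"
            )
    if rods:
        primitives["shrapnel"] = rods
        for name, group in vessels.items():
            if group:
                true_min[name] = min(
                    ellipse_rect_distance(e, rod) for e in group for rod in rods
                )
    return SceneGeometry(image_size=size, primitives=primitives, true_min_distances=true_min)


def rasterize_mask(scene: SceneGeometry, spec: PhantomSpec) -> np.ndarray:
    """Label each pixel whose centre lies inside a primitive.

    Classes are painted in ascending label order, so on overlap the class
    with the higher integer label (shrapnel last) wins.
    """
    size = scene.image_size
    yy, xx = np.mgrid[0:size, 0:size]
    xc, yc = xx + 0.5, yy + 0.5
    mask = np.zeros((size, size), dtype=np.uint8)
    for name, label in sorted(spec.class_table.items(), key=lambda kv: kv[1]):
        if label == 0:
            continue
        for prim in scene.primitives.get(name, []):
            mask[prim.contains(xc, yc)] = label
    return mask


def render_image(
    scene: SceneGeometry, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render the grayscale frame: class intensities times unit-mean speckle.

    Speckle is gamma-distributed with shape 1/cv² (mean 1, coefficient of
    variation ``speckle_strength``), applied multiplicatively per pixel and
    clipped to [0, 255].  Zero strength gives a piecewise-constant image.
    """
    mask = rasterize_mask(scene, spec)
    label_to_name = {v: k for k, v in spec.class_table.items()}
    base = np.zeros(mask.shape, dtype=float)
    for label, name in label_to_name.items():
        base[mask == label] = spec.intensity_table[name]
    s = spec.speckle_strength
    if s > 0:
        shape = 1.0 / (s * s)
        speckle = rng.gamma(shape, 1.0 / shape, size=mask.shape)
        base = base * speckle
    return np.clip(np.rint(base), 0, 255).astype(np.uint8)


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx * xx + yy * yy) <= r * r


def _most_interior_pixel(region: np.ndarray) -> tuple[int, int]:
    dist = ndimage.distance_transform_edt(region)
    flat = int(np.argmax(dist))  # argmax ties -> lowest row-major index (lex order)
    return np.unravel_index(flat, region.shape)


def perturb_mask(
    mask: np.ndarray,
    mode: str,
    magnitude: float,
    keep_nonempty: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Controlled mask corruption emulating segmentation-model bias.

    ``dilate`` grows every non-background class by a Euclidean disk of radius
    ``magnitude`` (overlaps resolved by class priority — higher label wins),
    mimicking a model that over-segments; ``erode`` shrinks symmetrically,
    mimicking tight masks; ``flip`` reassigns a ``magnitude`` fraction of
    boundary-adjacent pixels to the label of a random differing 4-neighbour.
    With ``keep_nonempty``, a class fully removed by erosion keeps its most
    interior pixel.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    mask = np.asarray(mask)
    labels = sorted(int(v) for v in np.unique(mask) if v != 0)
    if mode == "dilate":
        if int(magnitude) == 0:
            return mask.copy()
        selem = _disk(int(magnitude))
        out = mask.copy()
        background = mask == 0
        # growth claims background pixels only (original labels are never
        # reassigned, so no class can shrink); contested background goes to
        # the higher class because labels are painted in ascending order
        for label in labels:
            grown = ndimage.binary_dilation(mask == label, structure=selem)
            out[grown & background] = label
        return out
    if mode == "erode":
        if int(magnitude) == 0:
            return mask.copy()
        selem = _disk(int(magnitude))
        out = np.zeros_like(mask)
        for label in labels:
            region = mask == label
            shrunk = ndimage.binary_erosion(region, structure=selem)
            if keep_nonempty and not shrunk.any():
                r, c = _most_interior_pixel(region)
                shrunk = np.zeros_like(region)
                shrunk[r, c] = True
            out[shrunk] = label
        return out
    if mode == "flip":
        if rng is None:
            raise ValueError("flip mode requires an rng")
        if magnitude > 1:
            raise ValueError("flip magnitude is a fraction in [0, 1]")
        out = mask.copy()
        padded = np.pad(mask, 1, mode="edge")
        neighbours = np.stack(
            [padded[:-2, 1:-1], padded[2:, 1:-1], padded[1:-1, :-2], padded[1:-1, 2:]]
        )
        boundary = (neighbours != mask[None]).any(axis=0)
        rows, cols = np.nonzero(boundary)
        n_flip = int(round(magnitude * len(rows)))
        if n_flip == 0:
            return out
        pick = rng.choice(len(rows), size=n_flip, replace=False)
        for idx in pick:
            r, c = int(rows[idx]), int(cols[idx])
            options = neighbours[:, r, c]
            options = options[options != mask[r, c]]
            out[r, c] = rng.choice(options)
        return out
    raise ValueError(f"unknown perturbation mode {mode!r}")


def dataset_annotations(
    samples: list[PhantomSample], spec: PhantomSpec
) -> AnnotationSet:
    """Trace each sample's mask regions into a COCO-style annotation set.

    Polygons follow pixel-corner cracks, so re-rasterizing them with the
    centre-inside rule reproduces each mask exactly.
    """
    label_to_name = {v: k for k, v in spec.class_table.items() if v != 0}
    images, annotations = [], []
    categories = [Category(v, k) for k, v in spec.class_table.items() if v != 0]
    for i, sample in enumerate(samples):
        image_id = i + 1
        h, w = sample.mask.shape
        images.append(ImageInfo(image_id, f"{sample.sample_id}.png", w, h))
        for label in sorted(label_to_name):
            for poly in trace_binary_regions(sample.mask == label):
                annotations.append(
                    Annotation(image_id, label, tuple(map(tuple, poly.tolist())))
                )
    return AnnotationSet(images, categories, annotations)


def generate_dataset(
    spec: PhantomSpec, n: int, seed: int | None = None
) -> tuple[list[PhantomSample], AnnotationSet]:
    """Generate ``n`` reproducible phantom samples plus their annotations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base_seed = spec.seed if seed is None else seed
    samples = []
    for i in range(n):
        rng = np.random.default_rng([base_seed, i])
        scene = generate_scene(spec, rng)
        mask = rasterize_mask(scene, spec)
        image = render_image(scene, spec, rng)
        samples.append(
            PhantomSample(sample_id=f"sample_{i:04d}", image=image, mask=mask, scene=scene)
        )
    return samples, dataset_annotations(samples, spec)
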