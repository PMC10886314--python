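"""Boundary closest-point triage distances between shrapnel and features.

The triage score of a labeled mask is the minimum Euclidean distance from
the boundary of the shrapnel region to the boundary of the nearest
neurovascular feature (vein, artery, or nerve).  Boundaries are the class
pixels with at least one 4-connected neighbour outside the class (the image
border counts as outside); disconnected instances of a class are pooled.
Distances are measured between integer pixel coordinates (centres), so
diagonal neighbours are sqrt(2) apart, and are reported in pixels at the
mask's native resolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoundarySet",
    "FeatureDistance",
    "TriageResult",
    "TriageError",
    "extract_boundary",
    "min_distance_pair",
    "triage_distance",
    "triage_error",
    "render_overlay",
]


@dataclass(frozen=True)
class BoundarySet:
    """Pooled boundary pixels of one class, lexicographically sorted (row, col)."""

    label: int
    points: np.ndarray  # (n, 2) int array of (row, col)

    @property
    def empty(self) -> bool:
        return len(self.points) == 0


@dataclass(frozen=True)
class FeatureDistance:
    defined: bool
    distance: float | None = None
    point_shrapnel: tuple[int, int] | None = None
    point_feature: tuple[int, int] | None = None


@dataclass
class TriageResult:
    """Per-feature closest-pair distances and the overall triage score."""

    per_feature: dict[int, FeatureDistance]
    triage_score: float | None
    nearest_feature: int | None
    resolution: tuple[int, int]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "resolution": list(self.resolution),
            "triage_score": self.triage_score,
            "nearest_feature": self.nearest_feature,
            "per_feature": {
                str(k): {
                    "defined": v.defined,
                    "distance": v.distance,
                    "point_shrapnel": list(v.point_shrapnel) if v.point_shrapnel else None,
                    "point_feature": list(v.point_feature) if v.point_feature else None,
                }
                for k, v in self.per_feature.items()
            },
        }


@dataclass(frozen=True)
class TriageError:
    """Agreement between a predicted and a ground-truth triage score."""

    defined: bool
    difference: float | None = None  # absolute
    signed_difference: float | None = None  # pred - truth
    percent_error: float | None = None  # 100 * |diff| / truth
    failed_side: str | None = None  # "pred", "truth", or "both"


def extract_boundary(mask: np.ndarray, label: int) -> BoundarySet:
    """Boundary pixels of ``label``: class pixels with a 4-connected outside
    neighbour, the image border counting as outside.  All instances pooled.
    An absent class yields an empty set, not an error."""
    mask = np.asarray(mask)
    inside = mask == label
    if not inside.any():
        return BoundarySet(label, np.empty((0, 2), dtype=np.int64))
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = inside
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = inside & ~interior
    pts = np.argwhere(boundary)  # row-major -> (row, col) lexicographic order
    return BoundarySet(label, pts.astype(np.int64))


def min_distance_pair(
    a: BoundarySet, b: BoundarySet, chunk: int = 4096
) -> tuple[tuple[int, int], tuple[int, int], float]:
    """Exact closest pair between two boundary sets.

    Squared distances are computed in integer arithmetic (exact), minimised
    over all cross pairs in chunks.  Ties break to the lexicographically
    lowest (row, col) point of ``a``, then of ``b`` — both sets are stored
    pre-sorted, so the first minimising pair in scan order wins.
    """
    if a.empty or b.empty:
        raise ValueError("min_distance_pair requires non-empty boundary sets")
    pa = a.points.astype(np.int64)
    pb = b.points.astype(np.int64)
    best = np.iinfo(np.int64).max
    best_ai = best_bi = -1
    for start in range(0, len(pa), chunk):
        sub = pa[start : start + chunk]
        d2 = (
            (sub[:, 0:1] - pb[None, :, 0]) ** 2 + (sub[:, 1:2] - pb[None, :, 1]) ** 2
        )
        flat = int(np.argmin(d2))
        val = int(d2.flat[flat])
        if val < best:
            best = val
            best_ai = start + flat // len(pb)
            best_bi = flat % len(pb)
    return (
        (int(pa[best_ai, 0]), int(pa[best_ai, 1])),
        (int(pb[best_bi, 0]), int(pb[best_bi, 1])),
        float(np.sqrt(best)),
    )


def triage_distance(
    mask: np.ndarray,
    shrapnel_class: int,
    feature_classes: list[int],
) -> TriageResult:
    """Closest-pair distance from shrapnel to each feature; minimum = score.

    A feature absent from the mask (or absent shrapnel) gives an undefined
    per-feature entry; the triage score is undefined when shrapnel is absent
    or no feature is present.  The one-label-per-pixel mask encoding means
    regions cannot overlap; abutting regions give their boundary-pair
    distance (>= 1) unchanged.
    """
    if shrapnel_class in feature_classes:
        raise ValueError("shrapnel_class must not appear among feature_classes")
    mask = np.asarray(mask)
    shrapnel = extract_boundary(mask, shrapnel_class)
    per_feature: dict[int, FeatureDistance] = {}
    best: float | None = None
    nearest: int | None = None
    for label in feature_classes:
        feat = extract_boundary(mask, label)
        if shrapnel.empty or feat.empty:
            per_feature[label] = FeatureDistance(defined=False)
            continue
        ps, pf, dist = min_distance_pair(shrapnel, feat)
        per_feature[label] = FeatureDistance(True, dist, ps, pf)
        if best is None or dist < best:
            best, nearest = dist, label
    return TriageResult(
        per_feature=per_feature,
        triage_score=best,
        nearest_feature=nearest,
        resolution=mask.shape,
        metadata={"shrapnel_class": shrapnel_class, "feature_classes": list(feature_classes)},
    )


def render_overlay(mask: np.ndarray, result: TriageResult, path) -> None:
    """Save a PNG of the label mask with the minimum-distance segments drawn.

    Each defined feature gets a line between its closest point pair; the pair
    attaining the triage score is highlighted.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(mask, interpolation="nearest", cmap="viridis")
    for label, fd in result.per_feature.items():
        if not fd.defined:
            continue
        (r1, c1), (r2, c2) = fd.point_shrapnel, fd.point_feature
        is_min = label == result.nearest_feature
        ax.plot(
            [c1, c2],
            [r1, r2],
            color="cyan" if is_min else "white",
            linewidth=2.0 if is_min else 1.0,
        )
    if result.triage_score is not None:
        ax.set_title(f"triage score: {result.triage_score:.2f} px")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def triage_error(pred: TriageResult | float, truth: TriageResult | float) -> TriageError:
    """Absolute difference and percent error between two triage scores.

    percent_error = 100 * |pred - truth| / truth; a zero truth score leaves
    percent_error undefined while the difference is still reported.  An
    undefined score on either side yields an undefined result carrying which
    side failed.
    """
    ps = pred.triage_score if isinstance(pred, TriageResult) else pred
    ts = truth.triage_score if isinstance(truth, TriageResult) else truth
    if ps is None or ts is None:
        side = "both" if ps is None and ts is None else ("pred" if ps is None else "truth")
        return TriageError(defined=False, failed_side=side)
    diff = abs(ps - ts)
    pct = 100.0 * diff / ts if ts > 0 else None
    return TriageError(
        defined=True, difference=diff, signed_difference=ps - ts, percent_error=pct
    )
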