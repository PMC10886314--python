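"""Pixel-exact polygon tracing and rasterization for label masks.

Two matched primitives:

* :func:`trace_binary_regions` walks the cracks (pixel-corner edges) around
  each 4-connected region of a binary mask and returns closed polygons whose
  vertices lie on integer pixel corners.
* :func:`polygon_to_mask` rasterizes any polygon with the pixel-centre-inside
  rule under even-odd (crossing-number) parity.

For simply connected regions the two are exact inverses: rasterizing a traced
polygon reproduces the region pixel for pixel.  Coordinates follow the
package convention (x = column, y = row, origin top-left, corner coordinates;
pixel (r, c) has centre (c + 0.5, r + 0.5)).
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["trace_binary_regions", "polygon_to_mask", "polygons_to_mask"]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _trace_component(inside: np.ndarray) -> list[np.ndarray]:
    """Trace one binary component into closed corner-coordinate loops."""
    rows, cols = np.nonzero(inside)
    # Directed crack edges, region kept on the walker's right-hand side.
    # For inside pixel (r, c) with corners (c, r)..(c+1, r+1):
    #   outside above  -> (c,   r)   -> (c+1, r)
    #   outside right  -> (c+1, r)   -> (c+1, r+1)
    #   outside below  -> (c+1, r+1) -> (c,   r+1)
    #   outside left   -> (c,   r+1) -> (c,   r)
    h, w = inside.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = inside
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(p0: tuple[int, int], p1: tuple[int, int]) -> None:
        edges.setdefault(p0, []).append(p1)

    for r, c in zip(rows.tolist(), cols.tolist()):
        if not padded[r, c + 1]:  # above
            add((c, r), (c + 1, r))
        if not padded[r + 1, c + 2]:  # right
            add((c + 1, r), (c + 1, r + 1))
        if not padded[r + 2, c + 1]:  # below
            add((c + 1, r + 1), (c, r + 1))
        if not padded[r + 1, c]:  # left
            add((c, r + 1), (c, r))

    loops: list[np.ndarray] = []
    while edges:
        start = min(edges)
        loop = [start]
        prev_dir: tuple[int, int] | None = None
        cur = start
        while True:
            cands = edges[cur]
            if len(cands) == 1 or prev_dir is None:
                nxt = cands[0]
            else:
                # Pinch vertex: prefer the right turn (towards the region),
                # then straight, then left — keeps each loop simple.
                rd = (-prev_dir[1], prev_dir[0])
                order = [rd, prev_dir, (prev_dir[1], -prev_dir[0])]
                by_dir = {(p[0] - cur[0], p[1] - cur[1]): p for p in cands}
                nxt = next(by_dir[d] for d in order if d in by_dir)
            cands.remove(nxt)
            if not cands:
                del edges[cur]
            prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
            cur = nxt
            if cur == start:
                break
            loop.append(cur)
        loops.append(_simplify(np.asarray(loop, dtype=float)))
    return loops


def _simplify(loop: np.ndarray) -> np.ndarray:
    """Drop vertices interior to straight runs (all edges are axis-aligned)."""
    n = len(loop)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        a, b, c = loop[i - 1], loop[i], loop[(i + 1) % n]
        if (a[0] == b[0] == c[0]) or (a[1] == b[1] == c[1]):
            keep[i] = False
    return loop[keep]


def trace_binary_regions(binary: np.ndarray) -> list[np.ndarray]:
    """Trace every 4-connected region of ``binary`` into corner polygons.

    Returns one (n_vertices, 2) float array of (x, y) vertices per closed
    loop.  Simply connected regions yield exactly one loop each.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return []
    labeled, n = ndimage.label(binary, structure=_FOUR_CONN)
    out: list[np.ndarray] = []
    for idx in range(1, n + 1):
        out.extend(_trace_component(labeled == idx))
    return out


def polygon_to_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one polygon: pixel is set iff its centre is inside (even-odd).

    ``polygon`` is an (n, 2) array of (x, y) vertices in corner coordinates;
    ``shape`` is (height, width).  A centre is inside when a ray towards +x
    crosses the polygon an odd number of times (half-open rule on y, so shared
    edges never double-count).
    """
    poly = np.asarray(polygon, dtype=float)
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    if len(poly) < 3:
        return out
    x0, x1 = poly[:, 0], np.roll(poly[:, 0], -1)
    y0, y1 = poly[:, 1], np.roll(poly[:, 1], -1)
    r_lo = max(int(np.floor(poly[:, 1].min() - 0.5)), 0)
    r_hi = min(int(np.ceil(poly[:, 1].max())), h)
    nonhoriz = y0 != y1
    x0n, x1n, y0n, y1n = x0[nonhoriz], x1[nonhoriz], y0[nonhoriz], y1[nonhoriz]
    for r in range(r_lo, r_hi):
        yc = r + 0.5
        crosses = ((y0n <= yc) & (yc < y1n)) | ((y1n <= yc) & (yc < y0n))
        if not crosses.any():
            continue
        xi = x0n[crosses] + (yc - y0n[crosses]) * (x1n[crosses] - x0n[crosses]) / (
            y1n[crosses] - y0n[crosses]
        )
        xi.sort()
        # centre (c + 0.5) is inside iff an odd number of crossings lie to its right
        centers = np.arange(w) + 0.5
        count_right = len(xi) - np.searchsorted(xi, centers, side="right")
        out[r] = count_right % 2 == 1
    return out


def polygons_to_mask(
    polygons: list[tuple[int, np.ndarray]], shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize (label, polygon) pairs into an integer mask.

    Labels are painted in ascending order so the highest class wins overlaps.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    for label, poly in sorted(polygons, key=lambda t: t[0]):
        mask[polygon_to_mask(poly, shape)] = label
    return mask
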