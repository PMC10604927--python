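"""Shared geometry and mask-overlap evaluation.

Coordinate convention, used everywhere in the package: a point is
``(x, y) = (column, row)``, 0-based, with *y* increasing downward.
Contours are ordered counter-clockwise in this frame (positive shoelace
area) and the first vertex is not repeated.  Pixel centers sit at integer
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ContourPointSet",
    "NormalizedPointCloud",
    "extract_contour_vertices",
    "minmax_normalize",
    "denormalize",
    "rasterize_polygon",
    "offset_polygon",
    "polygon_area",
    "dsc",
    "jaccard",
]

# 4-connectivity structuring element, shared by component labelling and the
# boundary test so extracted boundaries stay closed and one pixel thin.
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class ContourPointSet:
    """Unordered set of boundary pixels of a segmented object.

    ``points`` is an ``(n, 2)`` float array of ``(x, y)`` pixel coordinates;
    ``source_image_size`` is ``(H, W)`` of the mask the points came from.
    """

    points: np.ndarray
    source_image_size: tuple[int, int]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
            raise ValueError("ContourPointSet requires a nonempty (n, 2) array")
        object.__setattr__(self, "points", pts)
        h, w = self.source_image_size
        if (pts[:, 0] < 0).any() or (pts[:, 0] > w - 1).any() or (
            pts[:, 1] < 0
        ).any() or (pts[:, 1] > h - 1).any():
            raise ValueError("contour points fall outside the image bounds")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class NormalizedPointCloud:
    """Points mapped into [-1, 1]^2 with the affine transform that did it.

    ``transform = (x_min, x_max, y_min, y_max)`` records the forward min-max
    map so it can be inverted exactly by :func:`denormalize`.
    """

    points: np.ndarray
    transform: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        x_min, x_max, y_min, y_max = self.transform
        if not (x_max > x_min and y_max > y_min):
            raise ValueError("transform must have x_max > x_min and y_max > y_min")

    def __len__(self) -> int:
        return len(self.points)


def extract_contour_vertices(mask: np.ndarray) -> ContourPointSet:
    """Boundary pixels of the largest 4-connected foreground component.

    A foreground pixel is a boundary pixel when at least one of its four
    edge-neighbors is background; the frame border counts as background.
    The result is an unordered point set (row-major scan order).
    """
    mask = np.asarray(mask)
    mask = mask > 0 if mask.dtype != bool else mask
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("mask has no foreground pixels")
    labels, n = ndimage.label(mask, structure=_STRUCT4)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        comp = labels == (int(np.argmax(counts)) + 1)
    else:
        comp = labels == 1
    # pad with background so the frame border counts as background
    padded = np.pad(comp, 1)
    interior = ndimage.binary_erosion(padded, structure=_STRUCT4)[1:-1, 1:-1]
    boundary = comp & ~interior
    ys, xs = np.nonzero(boundary)
    return ContourPointSet(
        points=np.column_stack([xs, ys]).astype(float),
        source_image_size=mask.shape,
    )


def minmax_normalize(points: ContourPointSet | np.ndarray) -> NormalizedPointCloud:
    """Map points into [-1, 1]^2 per axis, sending [min, max] -> [-1, 1]."""
    pts = points.points if isinstance(points, ContourPointSet) else np.asarray(points, float)
    x_min, y_min = pts.min(axis=0)
    x_max, y_max = pts.max(axis=0)
    if x_max == x_min:
        raise ValueError("degenerate x axis: all x coordinates equal")
    if y_max == y_min:
        raise ValueError("degenerate y axis: all y coordinates equal")
    out = np.empty_like(pts, dtype=float)
    out[:, 0] = 2.0 * (pts[:, 0] - x_min) / (x_max - x_min) - 1.0
    out[:, 1] = 2.0 * (pts[:, 1] - y_min) / (y_max - y_min) - 1.0
    return NormalizedPointCloud(points=out, transform=(x_min, x_max, y_min, y_max))


def denormalize(
    points: NormalizedPointCloud | np.ndarray,
    transform: tuple[float, float, float, float] | None = None,
) -> np.ndarray:
    """Exact inverse of :func:`minmax_normalize`.

    Accepts either a :class:`NormalizedPointCloud` or a raw ``(n, 2)`` array
    plus the stored ``transform``.
    """
    if isinstance(points, NormalizedPointCloud):
        pts, transform = points.points, points.transform
    else:
        pts = np.asarray(points, dtype=float)
        if transform is None:
            raise ValueError("transform required when passing a raw array")
    if len(pts) == 0:
        return pts.reshape(0, 2)
    x_min, x_max, y_min, y_max = transform
    out = np.empty_like(pts, dtype=float)
    out[:, 0] = (pts[:, 0] + 1.0) / 2.0 * (x_max - x_min) + x_min
    out[:, 1] = (pts[:, 1] + 1.0) / 2.0 * (y_max - y_min) + y_min
    return out


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area; positive for counter-clockwise order."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _segments_self_intersect(v: np.ndarray) -> bool:
    """True when any two non-adjacent closed-polygon edges properly cross."""
    n = len(v)
    a, b = v, np.roll(v, -1, axis=0)
    d = b - a
    for i in range(n):
        j = np.arange(i + 2, n if i > 0 else n - 1)
        if len(j) == 0:
            continue
        # cross products for segment-pair orientation tests, vectorized over j
        r, s = d[i], d[j]
        qp = a[j] - a[i]
        denom = r[0] * s[:, 1] - r[1] * s[:, 0]
        t_num = qp[:, 0] * s[:, 1] - qp[:, 1] * s[:, 0]
        u_num = qp[:, 0] * r[1] - qp[:, 1] * r[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = t_num / denom
            u = u_num / denom
        hit = (denom != 0) & (t > 1e-12) & (t < 1 - 1e-12) & (u > 1e-12) & (u < 1 - 1e-12)
        if hit.any():
            return True
    return False


def rasterize_polygon(
    vertices: np.ndarray, image_size: tuple[int, int]
) -> np.ndarray:
    """Fill a closed polygon onto a pixel grid (even-odd rule).

    A pixel is set when its center (integer ``(x, y)``) lies inside the
    polygon under the even-odd rule; centers lying exactly on the boundary
    are inside.  Self-intersecting input triggers a warning but is still
    filled even-odd.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    h, w = image_size
    if _segments_self_intersect(v):
        warnings.warn("self-intersecting polygon; applying even-odd fill", stacklevel=2)

    mask = np.zeros((h, w), dtype=bool)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    y_lo = max(int(np.floor(v[:, 1].min())), 0)
    y_hi = min(int(np.ceil(v[:, 1].max())), h - 1)
    px = np.arange(w, dtype=float)
    for py in range(y_lo, y_hi + 1):
        # half-open span rule avoids double-counting crossings at vertices
        crosses = (y1 <= py) != (y2 <= py)
        if not crosses.any():
            continue
        xi = x1[crosses] + (py - y1[crosses]) * (x2[crosses] - x1[crosses]) / (
            y2[crosses] - y1[crosses]
        )
        xi.sort()
        n_right = len(xi) - np.searchsorted(xi, px, side="right")
        mask[py] = (n_right % 2) == 1

    # boundary-touching pixel centers are inside by definition
    tol = 1e-9
    for i in range(len(v)):
        ax, ay, bx, by = x1[i], y1[i], x2[i], y2[i]
        lo_x = max(int(np.floor(min(ax, bx))), 0)
        hi_x = min(int(np.ceil(max(ax, bx))), w - 1)
        lo_y = max(int(np.floor(min(ay, by))), 0)
        hi_y = min(int(np.ceil(max(ay, by))), h - 1)
        if lo_x > hi_x or lo_y > hi_y:
            continue
        gx, gy = np.meshgrid(
            np.arange(lo_x, hi_x + 1, dtype=float),
            np.arange(lo_y, hi_y + 1, dtype=float),
        )
        dx, dy = bx - ax, by - ay
        L2 = dx * dx + dy * dy
        if L2 == 0:
            dist2 = (gx - ax) ** 2 + (gy - ay) ** 2
        else:
            t = np.clip(((gx - ax) * dx + (gy - ay) * dy) / L2, 0.0, 1.0)
            dist2 = (gx - ax - t * dx) ** 2 + (gy - ay - t * dy) ** 2
        on = dist2 <= tol
        if on.any():
            mask[lo_y : hi_y + 1, lo_x : hi_x + 1] |= on
    return mask


def offset_polygon(vertices: np.ndarray, distance: float) -> np.ndarray:
    """Offset a closed polygon along its outward normals.

    Positive distances grow the polygon regardless of input orientation.
    Used to undo the half-pixel bias of boundary-pixel extraction: boundary
    pixel centers lie about half a pixel inside the true region edge, so a
    contour fit to them under-covers the region by that margin.
    """
    v = np.asarray(vertices, dtype=float)
    tangent = np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)
    norms = np.linalg.norm(tangent, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tangent = tangent / norms
    # for counter-clockwise order (positive shoelace) in this frame the
    # outward normal of tangent (dx, dy) is (dy, -dx); flip if clockwise
    sign = 1.0 if polygon_area(v) >= 0 else -1.0
    normal = sign * np.column_stack([tangent[:, 1], -tangent[:, 0]])
    return v + distance * normal


def _as_bool_pair(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(mask_a), np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a > 0, b > 0


def dsc(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); 1 when both masks are empty."""
    a, b = _as_bool_pair(mask_a, mask_b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard similarity coefficient |A∩B|/|A∪B|; 1 when both masks are empty."""
    a, b = _as_bool_pair(mask_a, mask_b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union
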