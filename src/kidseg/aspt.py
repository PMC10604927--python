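"""Automatic searching polygon tracking (ASPT).

Turns the unordered boundary-pixel cloud of a coarse segmentation into an
ordered, optimized closed polygon — a principal-curve fit in which the
number of vertices is *discovered*, never supplied:

1. min-max normalization of the point cloud into [-1, 1]^2;
2. adaptive mean-shift clustering (per-point k-NN bandwidths, Gaussian
   kernel) whose modes become the polygon vertices — the mode count is a
   property of the data's density landscape, not an input;
3. angular ordering of the modes into a counter-clockwise polygon;
4. vertex optimization by cyclic coordinate descent on a penalized
   distance objective: average squared data distance Delta plus a
   curvature penalty, either the classical angle-based penalty
   ``CP(v_i) = r^2 (1 + cos gamma_i)`` or the averaged segment-distance
   penalty ``MP(v_i)`` that replaces it in the modified step;
5. chord-length parameterization of the result into the vertex sequence
   ``D = {(t_i, (v_x, v_y))}`` consumed by the contour-fitting network.

All geometry happens in normalized coordinates; callers denormalize with
the stored transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from kidseg.geometry import (
    ContourPointSet,
    NormalizedPointCloud,
    minmax_normalize,
    polygon_area,
    _segments_self_intersect,
)

__all__ = [
    "PolygonalCurve",
    "VertexOptState",
    "VertexSequence",
    "ASPTConfig",
    "ASPTResult",
    "data_radius",
    "adaptive_bandwidths",
    "mean_shift_modes",
    "order_vertices",
    "avg_sq_distance",
    "curvature_penalty_mp",
    "curvature_penalty_cp",
    "penalty_lambda",
    "penalized_distance",
    "total_objective",
    "optimize_vertices",
    "project_to_curve",
    "data_sequence",
    "resample_curve",
    "run_aspt",
]

logger = logging.getLogger(__name__)


@dataclass
class PolygonalCurve:
    """Closed polygon: ordered vertices, implied segment v_i -> v_{i+1} (cyclic)."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("a polygonal curve needs at least 3 (x, y) vertices")
        if (np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1) == 0).any():
            raise ValueError("consecutive vertices must be distinct")
        self.vertices = v

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def n_segments(self) -> int:
        return len(self.vertices)  # closed polygon: one segment per vertex

    def gamma(self) -> np.ndarray:
        """Interior turn angle at each vertex, in [0, pi]; pi = straight."""
        v = self.vertices
        prev = np.roll(v, 1, axis=0) - v
        nxt = np.roll(v, -1, axis=0) - v
        cosg = np.einsum("ij,ij->i", prev, nxt) / (
            np.linalg.norm(prev, axis=1) * np.linalg.norm(nxt, axis=1)
        )
        return np.arccos(np.clip(cosg, -1.0, 1.0))


@dataclass
class VertexSequence:
    """Ordered sequence D = {(t_i, (v_x, v_y))} with strictly increasing t."""

    t: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        c = np.asarray(self.coords, dtype=float)
        if len(t) != len(c):
            raise ValueError("t and coords must have equal length")
        if (np.diff(t) <= 0).any():
            raise ValueError("t must be strictly increasing")
        if t[0] < 0 or t[-1] > 1:
            raise ValueError("t must lie within [0, 1]")
        if not np.isfinite(c).all():
            raise ValueError("coordinates must be finite")
        self.t, self.coords = t, c

    def __len__(self) -> int:
        return len(self.t)

    def with_closure(self) -> "VertexSequence":
        """Append the first vertex again at t = 1 (for closed-contour fitting)."""
        if self.t[-1] >= 1.0:
            return self
        return VertexSequence(
            t=np.append(self.t, 1.0), coords=np.vstack([self.coords, self.coords[:1]])
        )


def data_radius(points: NormalizedPointCloud | np.ndarray) -> float:
    """Largest distance between any data point and the cloud centroid."""
    pts = points.points if isinstance(points, NormalizedPointCloud) else np.asarray(
        points, float
    )
    if len(pts) < 2:
        raise ValueError("data radius needs at least 2 points")
    r = float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).max())
    if r == 0.0:
        warnings.warn("all points identical: data radius is 0 (degenerate)", stacklevel=2)
    return r


def _pairwise_distances(pts: np.ndarray) -> np.ndarray:
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def adaptive_bandwidths(
    points: NormalizedPointCloud | np.ndarray, k_neighbors: int
) -> np.ndarray:
    """Per-point kernel bandwidth = distance to the k-th nearest neighbor.

    Duplicated points would give a zero bandwidth; those fall back to the
    smallest positive neighbor distance (with a warning).
    """
    pts = points.points if isinstance(points, NormalizedPointCloud) else np.asarray(
        points, float
    )
    n = len(pts)
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < point count {n}")
    dist = _pairwise_distances(pts)
    sorted_d = np.sort(dist, axis=1)
    h = sorted_d[:, k_neighbors]  # column 0 is the self-distance 0
    if (h == 0).any():
        positive = np.where(sorted_d > 0, sorted_d, np.inf).min(axis=1)
        if np.isinf(positive).all():
            raise ValueError("all points identical: bandwidths undefined")
        fallback = float(positive[np.isfinite(positive)].min())
        logger.warning(
            "%d duplicate-heavy points got zero k-NN bandwidth; using smallest "
            "positive neighbor distance %.3g", int((h == 0).sum()), fallback,
        )
        h = np.where(h == 0, fallback, h)
    return h


def mean_shift_modes(
    points: NormalizedPointCloud | np.ndarray,
    bandwidths: np.ndarray | float,
    tol: float = 1e-4,
    max_iter: int = 500,
    merge_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive Gaussian mean shift: every point ascends to a density mode.

    Uses the sample-point density estimator: the shifted mean at y weights
    each data point p_j by ``h_j^-(d+2) * exp(-||y - p_j||^2 / (2 h_j^2))``.
    Converged trajectories are merged into modes when closer than
    ``merge_radius`` (default: half the median bandwidth).  Returns
    ``(modes, labels)``; the number of modes is discovered, never supplied.
    """
    pts = points.points if isinstance(points, NormalizedPointCloud) else np.asarray(
        points, float
    )
    n, d = pts.shape
    if np.isscalar(bandwidths):
        h = np.full(n, float(bandwidths))
    else:
        h = np.asarray(bandwidths, dtype=float)
    if (h <= 0).any():
        raise ValueError("bandwidths must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if merge_radius is None:
        merge_radius = 0.5 * float(np.median(h))

    if n == 1:
        return pts.copy(), np.zeros(1, dtype=int)

    prefactor = h ** (-(d + 2))
    y = pts.copy()
    active = np.ones(n, dtype=bool)
    n_stuck = 0
    for _ in range(max_iter):
        if not active.any():
            break
        ya = y[active]
        diff = ya[:, None, :] - pts[None, :, :]
        sq = np.einsum("ijk,ijk->ij", diff, diff)
        w = prefactor[None, :] * np.exp(-sq / (2.0 * h[None, :] ** 2))
        new = (w @ pts) / w.sum(axis=1, keepdims=True)
        shift = np.linalg.norm(new - ya, axis=1)
        y[active] = new
        still = shift >= tol
        idx = np.nonzero(active)[0]
        active[idx[~still]] = False
    else:
        n_stuck = int(active.sum())
        if n_stuck:
            logger.warning("%d mean-shift trajectories hit max_iter", n_stuck)

    # greedy mode merging on the converged positions
    modes: list[np.ndarray] = []
    members: list[list[int]] = []
    labels = np.empty(n, dtype=int)
    for i in range(n):
        assigned = False
        for m, center in enumerate(modes):
            if np.linalg.norm(y[i] - center) < merge_radius:
                labels[i] = m
                members[m].append(i)
                assigned = True
                break
        if not assigned:
            modes.append(y[i].copy())
            members.append([i])
            labels[i] = len(modes) - 1
    mode_arr = np.array([y[m].mean(axis=0) for m in members])
    return mode_arr, labels


def order_vertices(modes: np.ndarray) -> PolygonalCurve:
    """Order modes into a counter-clockwise closed polygon.

    Primary rule: sort by polar angle about the centroid (ties broken by
    radius, ascending).  If the angular sort self-intersects (the mode set
    is not star-convex about its centroid), fall back to nearest-neighbor
    chaining from the lowest-angle mode.
    """
    modes = np.asarray(modes, dtype=float)
    if len(modes) < 3:
        raise ValueError("insufficient vertices: need at least 3 modes")
    center = modes.mean(axis=0)
    rel = modes - center
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    radii = np.linalg.norm(rel, axis=1)
    order = np.lexsort((radii, angles))
    ordered = modes[order]
    if _segments_self_intersect(ordered):
        start = order[0]
        remaining = set(range(len(modes)))
        chain = [start]
        remaining.discard(start)
        while remaining:
            last = modes[chain[-1]]
            nxt = min(remaining, key=lambda i: float(np.linalg.norm(modes[i] - last)))
            chain.append(nxt)
            remaining.discard(nxt)
        ordered = modes[chain]
    area = polygon_area(ordered)
    if abs(area) < 1e-12:
        warnings.warn("degenerate polygon: ordered modes are collinear", stacklevel=2)
    elif area < 0:
        ordered = ordered[::-1]
    return PolygonalCurve(vertices=ordered)


@dataclass
class VertexOptState:
    """Data cloud + current polygon + the curve partition the objective needs.

    Each data point is assigned once, to its nearest element of the closed
    polygon: the *interior* of a segment (the sets S_i, segment i running
    v_i -> v_{i+1}) when its projection falls strictly inside, or a vertex
    (the sets V_i) when the projection lands on an endpoint — the Voronoi
    partition of the curve into vertices and open segments.
    ``vertex_partition[j]`` is the vertex index or -1; ``segment_partition[j]``
    the segment index or -1; exactly one of the two is set per point.
    ``r`` is the data radius and ``lambda_prime`` the penalty adjustment
    constant (0.13).
    """

    data_points: np.ndarray
    curve: PolygonalCurve
    r: float
    lambda_prime: float = 0.13
    vertex_partition: np.ndarray = field(init=False)
    segment_partition: np.ndarray = field(init=False)
    _seg_dist2: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.data_points = np.asarray(self.data_points, dtype=float)
        if self.r <= 0:
            raise ValueError("data radius r must be positive")
        if self.lambda_prime < 0:
            raise ValueError("lambda_prime must be nonnegative")
        self.refresh_partitions()

    def refresh_partitions(self) -> None:
        vp, sp, d2 = _curve_partition(self.data_points, self.curve.vertices)
        self.vertex_partition = vp
        self.segment_partition = sp
        self._seg_dist2 = d2

    @property
    def n_vertices(self) -> int:
        return len(self.curve)

    @property
    def n_segments(self) -> int:
        return self.curve.n_segments


def _point_segment_sq_distances(
    pts: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Clipped squared distances (n, s) to closed-polygon segments + raw t."""
    a = v
    b = np.roll(v, -1, axis=0)
    ab = b - a  # (s, 2)
    ap = pts[:, None, :] - a[None, :, :]  # (n, s, 2)
    denom = np.einsum("ij,ij->i", ab, ab)
    t_raw = np.einsum("nsj,sj->ns", ap, ab) / denom[None, :]
    t = np.clip(t_raw, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    diff = pts[:, None, :] - closest
    return np.einsum("nsj,nsj->ns", diff, diff), t_raw


def _curve_partition(
    pts: np.ndarray, verts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign each point to its nearest curve element (vertex or segment).

    Returns ``(vertex_partition, segment_partition, seg_dist2)`` where the
    partitions hold -1 for points assigned to the other element kind.
    """
    iv = len(verts)
    d2, t_raw = _point_segment_sq_distances(pts, verts)
    nearest_seg = d2.argmin(axis=1)
    n = len(pts)
    t_star = t_raw[np.arange(n), nearest_seg]
    vertex_partition = np.full(n, -1, dtype=int)
    segment_partition = np.full(n, -1, dtype=int)
    interior = (t_star > 0.0) & (t_star < 1.0)
    segment_partition[interior] = nearest_seg[interior]
    at_start = ~interior & (t_star <= 0.0)
    at_end = ~interior & (t_star >= 1.0)
    vertex_partition[at_start] = nearest_seg[at_start]
    vertex_partition[at_end] = (nearest_seg[at_end] + 1) % iv
    return vertex_partition, segment_partition, d2


def avg_sq_distance(state: VertexOptState, vertex_index: int) -> float:
    """Average squared distance Delta_iv(v_i) = sigma- + tau + sigma+.

    tau sums squared distances of the points whose nearest curve element is
    vertex i; sigma+/- sum squared distances of the points assigned to the
    two incident segments (i and i-1) to those segments.  Every vertex of a
    closed polygon is interior, so both segment terms are always present;
    empty assignment sets contribute 0.
    """
    i = vertex_index
    pts = state.data_points
    v = state.curve.vertices
    iv = state.n_vertices
    in_vi = state.vertex_partition == i
    tau = float(np.sum(np.sum((pts[in_vi] - v[i]) ** 2, axis=1)))
    seg_plus = i  # segment v_i -> v_{i+1}
    seg_minus = (i - 1) % iv  # segment v_{i-1} -> v_i
    sp = float(state._seg_dist2[state.segment_partition == seg_plus, seg_plus].sum())
    sm = float(state._seg_dist2[state.segment_partition == seg_minus, seg_minus].sum())
    return sm + tau + sp


def curvature_penalty_cp(state: VertexOptState, vertex_index: int) -> float:
    """Classical angle penalty CP(v_i) = r^2 (1 + cos gamma_i)."""
    gamma_i = state.curve.gamma()[vertex_index]
    return state.r**2 * (1.0 + float(np.cos(gamma_i)))


def curvature_penalty_mp(state: VertexOptState, vertex_index: int) -> float:
    """Averaged penalty MP(v_i): mean over the `is` segments of the mean
    squared distance of each segment's assigned points to v_i.

    Segments with no assigned points contribute 0.  Always finite and
    nonnegative; scale-consistent with Delta_iv.
    """
    pts = state.data_points
    v_i = state.curve.vertices[vertex_index]
    n_seg = state.n_segments
    total = 0.0
    for s in range(n_seg):
        sel = state.segment_partition == s
        if sel.any():
            total += float(np.mean(np.sum((pts[sel] - v_i) ** 2, axis=1)))
    return total / n_seg


def penalty_lambda(state: VertexOptState) -> float:
    """Penalty coefficient lambda = lambda' * iv^(1/3) * sqrt(mean Delta) / r."""
    if state.r <= 0:
        raise ValueError("data radius r must be positive")
    iv = state.n_vertices
    mean_delta = np.mean([avg_sq_distance(state, i) for i in range(iv)])
    return state.lambda_prime * iv ** (1.0 / 3.0) * float(np.sqrt(mean_delta)) / state.r


def penalized_distance(
    state: VertexOptState,
    vertex_index: int,
    penalty: str = "mp",
    lam: float | None = None,
) -> float:
    """Per-vertex penalized distance G'_iv (MP penalty) or G_iv (CP penalty).

    ``G'_iv(v_i) = Delta_iv(v_i)/iv + lambda * MP(v_i)/(k+1)`` with k the
    segment count; the classical form uses CP with the same 1/(is+1)
    weighting.  ``lam`` short-circuits the lambda recomputation when the
    caller already holds it.
    """
    if penalty not in ("mp", "cp"):
        raise ValueError(f"unknown penalty {penalty!r}; expected 'mp' or 'cp'")
    if lam is None:
        lam = penalty_lambda(state)
    delta = avg_sq_distance(state, vertex_index)
    iv, k = state.n_vertices, state.n_segments
    if penalty == "mp":
        return delta / iv + lam * curvature_penalty_mp(state, vertex_index) / (k + 1)
    return delta / iv + lam * curvature_penalty_cp(state, vertex_index) / (k + 1)


def _objective_arrays(
    pts: np.ndarray, verts: np.ndarray, r: float, lambda_prime: float, penalty: str
) -> float:
    """Vectorized total objective; must agree with summing penalized_distance."""
    iv = len(verts)
    n = len(pts)
    vpart, spart, d2 = _curve_partition(pts, verts)
    on_vertex = vpart >= 0
    diffv = pts[on_vertex] - verts[vpart[on_vertex]]
    tau = np.bincount(
        vpart[on_vertex], weights=np.einsum("nj,nj->n", diffv, diffv), minlength=iv
    )
    on_seg = spart >= 0
    seg_sum = np.bincount(
        spart[on_seg], weights=d2[np.nonzero(on_seg)[0], spart[on_seg]], minlength=iv
    )
    delta = np.roll(seg_sum, 1) + tau + seg_sum
    lam = lambda_prime * iv ** (1.0 / 3.0) * float(np.sqrt(delta.mean())) / r
    if penalty == "mp":
        dv2_all = np.einsum("nij,nij->ni", pts[:, None, :] - verts[None, :, :],
                            pts[:, None, :] - verts[None, :, :])
        one_hot = np.zeros((n, iv))
        one_hot[on_seg, spart[on_seg]] = 1.0
        counts = one_hot.sum(axis=0)
        sums = one_hot.T @ dv2_all  # (segment, vertex) summed squared distances
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts[:, None] > 0, sums / counts[:, None], 0.0)
        pen = means.sum(axis=0) / iv
    else:
        prev = np.roll(verts, 1, axis=0) - verts
        nxt = np.roll(verts, -1, axis=0) - verts
        cosg = np.einsum("ij,ij->i", prev, nxt) / (
            np.linalg.norm(prev, axis=1) * np.linalg.norm(nxt, axis=1)
        )
        pen = r**2 * (1.0 + np.clip(cosg, -1.0, 1.0))
    return float((delta / iv + lam * pen / (iv + 1)).sum())


def total_objective(state: VertexOptState, penalty: str = "mp") -> float:
    """Sum of the per-vertex penalized distances over the whole polygon."""
    lam = penalty_lambda(state)
    return float(
        sum(penalized_distance(state, i, penalty, lam) for i in range(state.n_vertices))
    )


def optimize_vertices(
    state: VertexOptState,
    penalty: str = "mp",
    max_rounds: int = 10,
    rel_tol: float = 1e-3,
    search_radius: float | None = None,
) -> tuple[PolygonalCurve, list[float]]:
    """Cyclic coordinate descent on the vertex positions.

    Each vertex's x then y coordinate is minimized by bounded scalar search
    within ``+/- search_radius`` of its current value; the full objective
    (partitions and lambda recomputed) is evaluated for every candidate,
    and a move is accepted only if it does not increase the total.  Stops
    when the relative decrease over a full round drops below ``rel_tol``.
    Returns the optimized curve and the trace of accepted total objectives.
    """
    if search_radius is None:
        search_radius = 0.1 * state.r

    def objective_with(vidx: int, coord: int, value: float) -> float:
        verts = state.curve.vertices.copy()
        verts[vidx, coord] = value
        if (np.linalg.norm(np.roll(verts, -1, axis=0) - verts, axis=1) == 0).any():
            return np.inf
        return _objective_arrays(
            state.data_points, verts, state.r, state.lambda_prime, penalty
        )

    trace = [
        _objective_arrays(
            state.data_points, state.curve.vertices, state.r, state.lambda_prime, penalty
        )
    ]
    # a round's relative decrease never exceeds 1 (objective >= 0), so a
    # tolerance above 1 is satisfied before any round runs
    if rel_tol > 1.0:
        return state.curve, trace
    for _ in range(max_rounds):
        round_start = trace[-1]
        for i in range(state.n_vertices):
            for coord in (0, 1):
                x0 = state.curve.vertices[i, coord]
                res = minimize_scalar(
                    lambda v: objective_with(i, coord, v),
                    bounds=(x0 - search_radius, x0 + search_radius),
                    method="bounded",
                    options={"xatol": 1e-4 * max(state.r, 1.0), "maxiter": 25},
                )
                if res.fun <= trace[-1]:
                    state.curve.vertices[i, coord] = float(res.x)
                    state.refresh_partitions()
                    trace.append(float(res.fun))
        if trace[-1] > round_start + 1e-12:
            raise RuntimeError(
                "objective increased across an accepted round "
                f"({round_start} -> {trace[-1]}); this is a bug"
            )
        if round_start == 0 or (round_start - trace[-1]) / max(round_start, 1e-30) < rel_tol:
            break
    return state.curve, trace


@dataclass
class ASPTConfig:
    k_neighbors: int | None = None  # default max(5, ceil(2% of points))
    # None = adaptive per-point bandwidths; a float = plain MSC at that
    # bandwidth; "median" = plain MSC at the median adaptive bandwidth (the
    # one-factor-change counterpart used in component ablations)
    fixed_bandwidth: float | str | None = None
    penalty: str = "mp"  # "mp" = modified step, "cp" = classical
    lambda_prime: float = 0.13
    ms_tol: float = 1e-3
    ms_max_iter: int = 500
    max_rounds: int = 10
    rel_tol: float = 1e-3


@dataclass
class ASPTResult:
    sequence: VertexSequence  # normalized coordinates
    curve: PolygonalCurve
    transform: tuple[float, float, float, float]
    report: dict


def project_to_curve(points: np.ndarray, curve: PolygonalCurve) -> np.ndarray:
    """Chord-length position t in [0, 1) of each point's projection.

    Each point is projected onto its nearest closed-polygon segment; t is
    the normalized arc length from vertex 0 to that projection.  This is
    the principal-curve parameterization of the raw data by the fitted
    polygon, used to fit the smooth contour map to the data itself.
    """
    pts = np.asarray(points, dtype=float)
    v = curve.vertices
    seg = np.roll(v, -1, axis=0) - v
    seg_len = np.linalg.norm(seg, axis=1)
    perimeter = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    ap = pts[:, None, :] - v[None, :, :]
    denom = np.einsum("ij,ij->i", seg, seg)
    t_seg = np.clip(np.einsum("nsj,sj->ns", ap, seg) / denom[None, :], 0.0, 1.0)
    closest = v[None, :, :] + t_seg[..., None] * seg[None, :, :]
    diff = pts[:, None, :] - closest
    d2 = np.einsum("nsj,nsj->ns", diff, diff)
    nearest = d2.argmin(axis=1)
    arc = cum[nearest] + t_seg[np.arange(len(pts)), nearest] * seg_len[nearest]
    return np.mod(arc / perimeter, 1.0)


def data_sequence(points: np.ndarray, curve: PolygonalCurve) -> VertexSequence:
    """The data cloud ordered by its projection parameter along the curve.

    Ties in t (points projecting to the same arc position) are broken by
    minimal increments so the sequence stays strictly increasing.
    """
    pts = np.asarray(points, dtype=float)
    t = project_to_curve(pts, curve)
    order = np.argsort(t, kind="stable")
    ts = t[order].copy()
    for i in range(1, len(ts)):
        if ts[i] <= ts[i - 1]:
            ts[i] = ts[i - 1] + 1e-9
    ts = np.clip(ts, 0.0, np.nextafter(1.0, 0.0))
    return VertexSequence(t=ts, coords=pts[order])


def resample_curve(curve: PolygonalCurve, n_samples: int) -> VertexSequence:
    """Sample the closed polygon at n equally spaced chord-length positions.

    The samples lie exactly on the polygon edges with their chord-length t;
    a dense resampling constrains a smooth contour fit *between* vertices,
    not just at them.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be at least 4")
    v = curve.vertices
    seg = np.roll(v, -1, axis=0) - v
    seg_len = np.linalg.norm(seg, axis=1)
    perimeter = float(seg_len.sum())
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    t = np.arange(n_samples, dtype=float) / n_samples
    arc = t * perimeter
    idx = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0, len(v) - 1)
    frac = (arc - cum[idx]) / seg_len[idx]
    return VertexSequence(t=t, coords=v[idx] + seg[idx] * frac[:, None])


def chord_length_parameterization(curve: PolygonalCurve) -> VertexSequence:
    """t by normalized cumulative chord length: t_1 = 0, t_iv < 1."""
    v = curve.vertices
    seg_len = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
    perimeter = float(seg_len.sum())
    t = np.concatenate([[0.0], np.cumsum(seg_len[:-1])]) / perimeter
    return VertexSequence(t=t, coords=v.copy())


def run_aspt(
    points: ContourPointSet | np.ndarray, config: ASPTConfig | None = None
) -> ASPTResult:
    """Full refinement chain: normalize, cluster, order, optimize, parameterize.

    The vertex count is discovered by the mean-shift stage.  Raises when the
    clustering yields fewer than 3 modes (use a smaller ``k_neighbors``).
    """
    config = config or ASPTConfig()
    raw = points.points if isinstance(points, ContourPointSet) else np.asarray(points, float)
    if len(raw) < 3:
        raise ValueError("need at least 3 boundary points")
    cloud = minmax_normalize(raw)
    pts = cloud.points
    n = len(pts)
    k = config.k_neighbors or max(5, int(np.ceil(0.02 * n)))
    k = min(k, n - 1)
    h = adaptive_bandwidths(pts, k)
    bandwidths: np.ndarray | float
    if config.fixed_bandwidth is None:
        bandwidths = h
        merge_radius = None
    else:
        fb = float(np.median(h)) if config.fixed_bandwidth == "median" else float(
            config.fixed_bandwidth
        )
        bandwidths = fb
        merge_radius = 0.5 * fb
    modes, labels = mean_shift_modes(
        pts, bandwidths, tol=config.ms_tol, max_iter=config.ms_max_iter,
        merge_radius=merge_radius,
    )
    if len(modes) < 3:
        raise ValueError(
            f"mean shift found only {len(modes)} mode(s); try smaller k_neighbors"
        )
    curve = order_vertices(modes)
    state = VertexOptState(pts, curve, data_radius(pts), config.lambda_prime)
    curve, trace = optimize_vertices(
        state,
        penalty=config.penalty,
        max_rounds=config.max_rounds,
        rel_tol=config.rel_tol,
        search_radius=0.5 * float(np.median(h)),
    )
    sequence = chord_length_parameterization(curve)
    report = {
        "n_points": int(n),
        "k_neighbors": int(k),
        "n_modes": int(len(modes)),
        "penalty": config.penalty,
        "adaptive_bandwidth": config.fixed_bandwidth is None,
        "n_accepted_moves": len(trace) - 1,
        "initial_objective": trace[0],
        "final_objective": trace[-1],
    }
    return ASPTResult(sequence=sequence, curve=curve, transform=cloud.transform, report=report)
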