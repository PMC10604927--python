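"""Independent brute-force oracles for the polygon-tracking objective.

Deliberately written as plain loops with exact point-to-segment distances,
sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def point_segment_distance_sq(p, a, b) -> float:
    px, py = p
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    if L2 == 0:
        return (px - ax) ** 2 + (py - ay) ** 2
    t = ((px - ax) * dx + (py - ay) * dy) / L2
    t = max(0.0, min(1.0, t))
    cx, cy = ax + t * dx, ay + t * dy
    return (px - cx) ** 2 + (py - cy) ** 2


def _segment_projection_param(p, a, b) -> float:
    dx, dy = b[0] - a[0], b[1] - a[1]
    L2 = dx * dx + dy * dy
    if L2 == 0:
        return 0.0
    return ((p[0] - a[0]) * dx + (p[1] - a[1]) * dy) / L2


def partitions(points, vertices):
    """Voronoi partition of the closed curve: vertex or segment per point.

    A point belongs to a segment's set when its projection onto the nearest
    segment falls strictly inside it, otherwise to the vertex at the
    endpoint the projection clips to.  Returns (vpart, spart) with -1 for
    the assignment kind that does not apply.
    """
    iv = len(vertices)
    vpart, spart = [], []
    for p in points:
        ds = [
            point_segment_distance_sq(p, vertices[s], vertices[(s + 1) % iv])
            for s in range(iv)
        ]
        s_near = int(np.argmin(ds))
        t = _segment_projection_param(p, vertices[s_near], vertices[(s_near + 1) % iv])
        if 0.0 < t < 1.0:
            vpart.append(-1)
            spart.append(s_near)
        elif t <= 0.0:
            vpart.append(s_near)
            spart.append(-1)
        else:
            vpart.append((s_near + 1) % iv)
            spart.append(-1)
    return vpart, spart


def delta(points, vertices, i) -> float:
    """Average squared distance Delta_iv(v_i) = sigma- + tau + sigma+."""
    iv = len(vertices)
    vpart, spart = partitions(points, vertices)
    tau = sum(
        (p[0] - vertices[i][0]) ** 2 + (p[1] - vertices[i][1]) ** 2
        for p, vp in zip(points, vpart)
        if vp == i
    )
    seg_plus, seg_minus = i, (i - 1) % iv
    sp = sum(
        point_segment_distance_sq(p, vertices[seg_plus], vertices[(seg_plus + 1) % iv])
        for p, s in zip(points, spart)
        if s == seg_plus
    )
    sm = sum(
        point_segment_distance_sq(p, vertices[seg_minus], vertices[(seg_minus + 1) % iv])
        for p, s in zip(points, spart)
        if s == seg_minus
    )
    return sm + tau + sp


def mp(points, vertices, i) -> float:
    """Averaged curvature penalty MP(v_i)."""
    iv = len(vertices)
    _, spart = partitions(points, vertices)
    total = 0.0
    for s in range(iv):
        members = [p for p, sp_ in zip(points, spart) if sp_ == s]
        if members:
            total += float(
                np.mean(
                    [
                        (p[0] - vertices[i][0]) ** 2 + (p[1] - vertices[i][1]) ** 2
                        for p in members
                    ]
                )
            )
    return total / iv


def cp(vertices, i, r) -> float:
    """Angle-based curvature penalty CP(v_i) = r^2 (1 + cos gamma_i)."""
    iv = len(vertices)
    v = vertices[i]
    a = vertices[(i - 1) % iv]
    b = vertices[(i + 1) % iv]
    va = (a[0] - v[0], a[1] - v[1])
    vb = (b[0] - v[0], b[1] - v[1])
    cosg = (va[0] * vb[0] + va[1] * vb[1]) / (
        math.hypot(*va) * math.hypot(*vb)
    )
    cosg = max(-1.0, min(1.0, cosg))
    return r * r * (1.0 + cosg)


def lam(points, vertices, r, lambda_prime=0.13) -> float:
    iv = len(vertices)
    mean_delta = np.mean([delta(points, vertices, i) for i in range(iv)])
    return lambda_prime * iv ** (1.0 / 3.0) * math.sqrt(mean_delta) / r


def g_prime(points, vertices, i, r, lambda_prime=0.13) -> float:
    iv = len(vertices)
    return delta(points, vertices, i) / iv + lam(points, vertices, r, lambda_prime) * mp(
        points, vertices, i
    ) / (iv + 1)


def g_classic(points, vertices, i, r, lambda_prime=0.13) -> float:
    iv = len(vertices)
    return delta(points, vertices, i) / iv + lam(points, vertices, r, lambda_prime) * cp(
        vertices, i, r
    ) / (iv + 1)


def kde_sample_point(y, points, bandwidths) -> float:
    """Adaptive (sample-point) Gaussian KDE, up to a constant factor."""
    total = 0.0
    d = len(y)
    for p, h in zip(points, bandwidths):
        sq = sum((yi - pi) ** 2 for yi, pi in zip(y, p))
        total += h ** (-d) * math.exp(-sq / (2 * h * h))
    return total


def kde_grid_argmax(points, bandwidths, lo, hi, n_grid=200):
    """Grid argmax of the adaptive KDE over a per-axis [lo_i, hi_i] box.

    ``lo``/``hi`` may be scalars (shared by all axes) or length-d vectors.
    """
    points = np.asarray(points, float)
    d = points.shape[1]
    lo = np.broadcast_to(np.asarray(lo, float), (d,))
    hi = np.broadcast_to(np.asarray(hi, float), (d,))
    axes = [np.linspace(lo[i], hi[i], n_grid) for i in range(d)]
    if d == 1:
        vals = [kde_sample_point((x,), points, bandwidths) for x in axes[0]]
        return np.array([axes[0][int(np.argmax(vals))]])
    best, best_v = None, -1.0
    for x in axes[0]:
        for y in axes[1]:
            v = kde_sample_point((x, y), points, bandwidths)
            if v > best_v:
                best, best_v = (x, y), v
    return np.array(best)
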