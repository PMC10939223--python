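"""Brute-force geometric oracles, independent of the package kernels."""

import numpy as np


def brute_force_line_hits(origin, direction, vertices, faces):
    """All line-mesh intersection parameters via scalar plane/half-space tests."""
    ts = []
    for f in faces:
        a, b, c = vertices[f]
        n = np.cross(b - a, c - a)
        denom = n @ direction
        if abs(denom) < 1e-12:
            continue
        t = (n @ (a - origin)) / denom
        p = origin + t * direction
        s1 = np.cross(b - a, p - a) @ n
        s2 = np.cross(c - b, p - b) @ n
        s3 = np.cross(a - c, p - c) @ n
        if s1 >= -1e-12 and s2 >= -1e-12 and s3 >= -1e-12:
            ts.append(t)
    ts = sorted(ts)
    # collapse duplicates from shared edges
    out = []
    for t in ts:
        if not out or t - out[-1] > 1e-9:
            out.append(t)
    return out


def _point_segment_distance(p, a, b):
    ab = b - a
    t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t * ab))


def point_triangle_distance_indep(p, a, b, c):
    """Plane-projection + segment-clamp formulation (independent of the
    region-classification kernel used by the package)."""
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n)
    if nn < 1e-15:
        return min(_point_segment_distance(p, a, b),
                   _point_segment_distance(p, b, c),
                   _point_segment_distance(p, c, a))
    n = n / nn
    proj = p - ((p - a) @ n) * n
    # barycentric test of the projection
    v0, v1, v2 = b - a, c - a, proj - a
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    if v >= 0 and w >= 0 and v + w <= 1:
        return abs((p - a) @ n)
    return min(_point_segment_distance(p, a, b),
               _point_segment_distance(p, b, c),
               _point_segment_distance(p, c, a))


def brute_force_containment(point, vertices, faces, rng):
    """Inside test by ray-crossing parity along a random direction."""
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    hits = brute_force_line_hits(point, d, vertices, faces)
    return sum(1 for t in hits if t > 0) % 2 == 1
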