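"""Independent geometry oracles: Sutherland-Hodgman clipping + shoelace area.

Deliberately free of shapely so they can cross-check the tiling module.
"""

from __future__ import annotations


def shoelace_area(vertices) -> float:
    n = len(vertices)
    s = 0.0
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def clip_polygon_to_rect(vertices, x0: float, y0: float, x1: float, y1: float):
    """Sutherland-Hodgman clip of a polygon against an axis-aligned rectangle."""

    def clip_edge(poly, inside, intersect):
        out = []
        n = len(poly)
        for i in range(n):
            cur, nxt = poly[i], poly[(i + 1) % n]
            cur_in, nxt_in = inside(cur), inside(nxt)
            if cur_in:
                out.append(cur)
                if not nxt_in:
                    out.append(intersect(cur, nxt))
            elif nxt_in:
                out.append(intersect(cur, nxt))
        return out

    def x_cross(p, q, x):
        t = (x - p[0]) / (q[0] - p[0])
        return (x, p[1] + t * (q[1] - p[1]))

    def y_cross(p, q, y):
        t = (y - p[1]) / (q[1] - p[1])
        return (p[0] + t * (q[0] - p[0]), y)

    poly = list(vertices)
    for inside, intersect in [
        (lambda p: p[0] >= x0, lambda p, q: x_cross(p, q, x0)),
        (lambda p: p[0] <= x1, lambda p, q: x_cross(p, q, x1)),
        (lambda p: p[1] >= y0, lambda p, q: y_cross(p, q, y0)),
        (lambda p: p[1] <= y1, lambda p, q: y_cross(p, q, y1)),
    ]:
        if not poly:
            return []
        poly = clip_edge(poly, inside, intersect)
    return poly


def rect_intersection_fraction(vertices, x0, y0, size) -> float:
    """Area fraction of the size x size square at (x0, y0) covered by the polygon.

    Exact for convex polygons and for star-shaped simple polygons whose clip
    against an axis-aligned rectangle stays simple (the shapes used in tests).
    """
    clipped = clip_polygon_to_rect(vertices, x0, y0, x0 + size, y0 + size)
    if len(clipped) < 3:
        return 0.0
    return shoelace_area(clipped) / float(size * size)


def brute_force_tiling(vertices, slide_w, slide_h, patch, stride, min_frac):
    """Enumerate every stride-lattice origin on the slide and keep qualifying
    patches — the from-scratch counterpart of the tiling module."""
    kept = []
    for y0 in range(0, slide_h - patch + 1, stride):
        for x0 in range(0, slide_w - patch + 1, stride):
            frac = rect_intersection_fraction(vertices, x0, y0, patch)
            if frac >= min_frac:
                kept.append((x0, y0, frac))
    return kept
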