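"""Independent brute-force point-in-polygon zone oracle for the error grid.

Ray-casting on the explicit zone polygons, zones checked in A->E order so a
boundary point falls to the safer zone — a deliberately separate code path
from the piecewise-boundary classifier in the package.
"""

from __future__ import annotations

ZONE_ORDER = ("A", "B", "C", "D", "E")


def _ring_coords(geom):
    """Exterior rings of a shapely Polygon/MultiPolygon as coordinate lists."""
    if geom.geom_type == "Polygon":
        geoms = [geom]
    else:
        geoms = list(geom.geoms)
    return [list(g.exterior.coords) for g in geoms if not g.is_empty]


def _point_in_ring(x, y, ring, eps=1e-9):
    """Crossing-number test; points within eps of an edge count as inside."""
    inside = False
    n = len(ring)
    for i in range(n - 1):
        x1, y1 = ring[i]
        x2, y2 = ring[i + 1]
        # on-segment check (inclusive boundary)
        dx, dy = x2 - x1, y2 - y1
        seg2 = dx * dx + dy * dy
        if seg2 > 0:
            t = ((x - x1) * dx + (y - y1) * dy) / seg2
            if 0.0 <= t <= 1.0:
                px, py = x1 + t * dx, y1 + t * dy
                if (x - px) ** 2 + (y - py) ** 2 < eps * eps:
                    return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def oracle_zone(reference, meter, polygons):
    """Zone of one point via brute-force ray casting, safer zone on ties."""
    for z in ZONE_ORDER:
        for ring in _ring_coords(polygons[z]):
            if _point_in_ring(reference, meter, ring):
                return z
    raise AssertionError(f"point ({reference}, {meter}) in no zone polygon")
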