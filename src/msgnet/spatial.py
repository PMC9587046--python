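"""Scenario classification: group formation, home range, NDVI tertiles, zone.

Coordinates are planar metres throughout (projected; the study landscape is
small enough that geodesic distortion is negligible).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import ConvexHull, cKDTree
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Point, Polygon

from .data import HABITATS, AnimalGroup, Sighting, ValidationError

__all__ = [
    "HomeRange",
    "form_groups",
    "form_groups_by_date",
    "mcp_home_range",
    "classify_lhr",
    "bin_ndvi",
    "ndvi_tertile_bounds",
    "classify_zone",
]


@dataclass(frozen=True)
class HomeRange:
    """A convex-hull home range at a given isopleth (fraction of locations
    retained before hulling)."""

    vertices: np.ndarray  # (k, 2), counter-clockwise
    isopleth: float
    source_points: int

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    def covers(self, x: float, y: float) -> bool:
        """Point-in-polygon with boundary points counting as inside."""
        return self.polygon.covers(Point(x, y))


# ---------------------------------------------------------------------------
# Group formation
# ---------------------------------------------------------------------------


def form_groups(
    sightings: Sequence[Sighting],
    radius: float = 50.0,
    rule: Literal["chain", "clique"] = "chain",
    id_prefix: str = "g",
) -> list[AnimalGroup]:
    """Aggregate sightings into animal groups.

    Under the default ``chain`` rule two sightings belong to the same group
    when they are linked by a chain of pairwise distances <= ``radius``
    (single linkage / connected components) — this mirrors the field practice
    of scanning outward around each detection.  ``clique`` instead requires a
    new sighting to lie within ``radius`` of *every* current member (greedy
    complete linkage in input order), a stricter alternative for sensitivity
    checks.

    Group habitat is the modal habitat of the member sightings (ties broken
    by the fixed habitat ordering), the group location is the unweighted
    centroid, and per-species counts are summed.  Callers should pass
    sightings from a single survey occasion; :func:`form_groups_by_date`
    partitions by date first.
    """
    if radius < 0:
        raise ValidationError(f"radius must be >= 0, got {radius}")
    if not sightings:
        return []
    xy = np.array([(s.x, s.y) for s in sightings])
    n = len(sightings)
    if rule == "chain":
        pairs = cKDTree(xy).query_pairs(r=radius, output_type="ndarray")
        if len(pairs):
            g = coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
            )
        else:
            g = coo_matrix((n, n))
        _, labels = connected_components(g, directed=False)
    elif rule == "clique":
        labels = np.full(n, -1)
        members: list[list[int]] = []
        for i in range(n):
            for gi, idxs in enumerate(members):
                d = np.hypot(*(xy[idxs] - xy[i]).T)
                if (d <= radius).all():
                    idxs.append(i)
                    labels[i] = gi
                    break
            else:
                members.append([i])
                labels[i] = len(members) - 1
    else:
        raise ValidationError(f"unknown grouping rule {rule!r}")

    groups: list[AnimalGroup] = []
    # deterministic group numbering: by first member index
    first_seen: dict[int, int] = {}
    for i in range(n):
        first_seen.setdefault(labels[i], i)
    for gi in sorted(first_seen, key=first_seen.get):
        idxs = np.flatnonzero(labels == gi)
        counts: dict[str, int] = {}
        for i in idxs:
            s = sightings[i]
            counts[s.species] = counts.get(s.species, 0) + s.count
        habs = Counter(sightings[i].habitat for i in idxs)
        top = max(habs.values())
        habitat = next(h for h in HABITATS if habs.get(h) == top)
        cx, cy = xy[idxs].mean(axis=0)
        groups.append(
            AnimalGroup(
                group_id=f"{id_prefix}{len(groups):05d}",
                members=counts,
                habitat=habitat,
                x=float(cx),
                y=float(cy),
                date=sightings[int(idxs[0])].date,
            )
        )
    return groups


def form_groups_by_date(
    sightings: Sequence[Sighting], radius: float = 50.0, rule: str = "chain"
) -> list[AnimalGroup]:
    """Partition sightings by calendar date, then form groups per occasion."""
    by_date: dict = {}
    for s in sightings:
        by_date.setdefault(s.date, []).append(s)
    groups: list[AnimalGroup] = []
    for k, day in enumerate(sorted(by_date)):
        groups.extend(
            form_groups(by_date[day], radius=radius, rule=rule, id_prefix=f"d{k:03d}_g")
        )
    return groups


# ---------------------------------------------------------------------------
# Minimum convex polygon home range
# ---------------------------------------------------------------------------


def mcp_home_range(
    points: Sequence[Sequence[float]] | np.ndarray, isopleth: float = 0.85
) -> HomeRange:
    """Minimum-convex-polygon home range at the given isopleth.

    The ceil((1 - isopleth) * n) points farthest from the arithmetic mean
    centre are discarded (ties broken by input order: the earlier point is
    kept), and the convex hull of the remainder is returned.  Isopleth 1.0 is
    the plain convex hull of all points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    n = len(pts)
    if not 0 < isopleth <= 1:
        raise ValidationError("isopleth must be in (0, 1]")
    # epsilon guards the representation error of (1 - isopleth)
    n_drop = math.ceil((1.0 - isopleth) * n - 1e-9)
    n_keep = n - n_drop
    if n_keep < 3:
        raise ValidationError(
            f"MCP needs >= 3 retained points, have {n_keep} of {n} at isopleth {isopleth}"
        )
    centre = pts.mean(axis=0)
    dist = np.hypot(*(pts - centre).T)
    keep = np.sort(np.argsort(dist, kind="stable")[:n_keep])
    kept = pts[keep]
    hull = ConvexHull(kept)
    return HomeRange(vertices=kept[hull.vertices], isopleth=isopleth, source_points=n)


def classify_lhr(groups: Iterable[AnimalGroup], hr: HomeRange) -> list[AnimalGroup]:
    """Set ``in_lhr`` on every group from its centroid; boundary counts inside."""
    out = []
    for g in groups:
        if g.x is None or g.y is None:
            raise ValidationError(f"group {g.group_id}: no centroid coordinates")
        g.in_lhr = bool(hr.covers(g.x, g.y))
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# NDVI tertiles
# ---------------------------------------------------------------------------


def ndvi_tertile_bounds(values: np.ndarray) -> tuple[float, float]:
    """Empirical tertile boundaries (1/3 and 2/3 quantiles, type-7 linear
    interpolation), yielding three equal-sized classes on distinct values."""
    values = np.asarray(values, dtype=float)
    q33, q67 = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    return float(q33), float(q67)


def ndvi_classes_for(values: np.ndarray) -> list[str]:
    """Tertile class per value; boundary values fall to the lower class."""
    values = np.asarray(values, dtype=float)
    if values.size and np.ptp(values) == 0.0:
        raise ValidationError(
            "degenerate NDVI distribution: all values identical, tertiles undefined"
        )
    q33, q67 = ndvi_tertile_bounds(values)
    return [
        "small" if v <= q33 else ("medium" if v <= q67 else "large") for v in values
    ]


def bin_ndvi(groups: Sequence[AnimalGroup]) -> list[AnimalGroup]:
    """Bin group-level NDVI into small/medium/large tertile classes."""
    missing = [g.group_id for g in groups if g.ndvi_value is None]
    if missing:
        raise ValidationError(f"groups lacking ndvi_value: {missing}")
    classes = ndvi_classes_for(np.array([g.ndvi_value for g in groups]))
    for g, c in zip(groups, classes):
        g.ndvi_class = c
    return list(groups)


# ---------------------------------------------------------------------------
# Core / edge zone
# ---------------------------------------------------------------------------


def classify_zone(
    groups: Iterable[AnimalGroup],
    boundary: Polygon | Sequence[Sequence[float]],
    buffer: float = 2000.0,
) -> list[AnimalGroup]:
    """Zone = ``core`` when the centroid lies inside the boundary polygon and
    more than ``buffer`` metres from its outline, else ``edge``."""
    poly = boundary if isinstance(boundary, Polygon) else Polygon(boundary)
    out = []
    for g in groups:
        if g.x is None or g.y is None:
            raise ValidationError(f"group {g.group_id}: no centroid coordinates")
        p = Point(g.x, g.y)
        inside = poly.covers(p)
        g.zone = "core" if inside and poly.exterior.distance(p) > buffer else "edge"
        out.append(g)
    return out
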