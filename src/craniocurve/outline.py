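"""Skull outline extraction from a surface mesh.

Intersecting the head surface with the analysis plane yields one or more
closed loops; the skull cross-section is taken as the loop with the largest
enclosed area (a slice may also clip ears or noise blobs).  The outline is
kept as an ordered counter-clockwise polygon in plane-local (u, v)
coordinates, from which the area centroid (the "centre of mass" of the
cross-section) and the occipital start point of the polar sweep are
derived.

The start construction: one line joins the projected left and right
exocanthion; the perpendicular bisector of that segment is intersected with
the outline, and of its two crossings the posterior one (behind the eyes,
on the occiput) starts the curve.  The sweep direction is chosen so the
patient's right side is passed in the first half-turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import trimesh
from shapely.geometry import Point, Polygon

from .errors import (
    DegenerateOutline,
    EmptySlice,
    OpenContour,
    StartNotFound,
)
from .geometry import CuttingPlane, LandmarkSet, to_plane_coords

__all__ = ["Outline", "CurveFrame", "slice_surface", "area_centroid", "locate_start"]


@dataclass(frozen=True)
class Outline:
    """Closed, ordered 2-D polygon (mm) in cutting-plane coordinates.

    ``vertices`` is (n, 2) with n >= 3; closure is implicit (first vertex is
    not repeated).  Orientation is counter-clockwise in (u, v).
    """

    vertices: np.ndarray
    plane: CuttingPlane

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise DegenerateOutline(f"outline needs >=3 2-D vertices, got shape {v.shape}")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.polygon.area)


@dataclass(frozen=True)
class CurveFrame:
    """Pole and angular reference of the polar sweep.

    ``center`` is the area centroid of the outline; ``start_direction`` the
    unit vector from the centre toward the occipital start point;
    ``right_first_sign`` is +1 for a counter-clockwise sweep in (u, v) and
    -1 for clockwise, chosen so the patient's right is passed first.
    """

    center: np.ndarray
    start_direction: np.ndarray
    right_first_sign: int
    start_point: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(2))
        sd = np.asarray(self.start_direction, dtype=float).reshape(2)
        n = np.linalg.norm(sd)
        object.__setattr__(self, "start_direction", sd / n)
        object.__setattr__(self, "start_point", np.asarray(self.start_point, dtype=float).reshape(2))
        if self.right_first_sign not in (-1, 1):
            raise ValueError("right_first_sign must be +1 or -1")


def _loop_signed_area(uv: np.ndarray) -> float:
    x, y = uv[:, 0], uv[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def slice_surface(mesh: trimesh.Trimesh, plane: CuttingPlane) -> Outline:
    """Intersect ``mesh`` with ``plane`` and return the largest closed loop.

    Raises :class:`EmptySlice` when the plane misses the surface and
    :class:`OpenContour` when only open polylines are produced (surface not
    closed around the vault at this height).
    """
    section = mesh.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if section is None or len(section.entities) == 0:
        raise EmptySlice("cutting plane does not intersect the surface")

    best: np.ndarray | None = None
    best_area = 0.0
    saw_open = False
    for points in section.discrete:
        pts = np.asarray(points, dtype=float)
        if len(pts) < 4 or not np.allclose(pts[0], pts[-1], atol=1e-8):
            saw_open = True
            continue
        uv = to_plane_coords(pts[:-1], plane)
        area = abs(_loop_signed_area(uv))
        if area > best_area:
            best_area = area
            best = uv
    if best is None:
        if saw_open:
            raise OpenContour("plane section produced only open polylines")
        raise EmptySlice("plane section produced no usable loop")
    if _loop_signed_area(best) < 0:
        best = best[::-1]
    # drop consecutive duplicates introduced by shared mesh vertices
    keep = np.ones(len(best), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(best, axis=0), axis=1) > 1e-12
    best = best[keep]
    if len(best) < 3:
        raise DegenerateOutline("slice loop degenerate after deduplication")
    return Outline(vertices=best, plane=plane)


def area_centroid(outline: Outline) -> np.ndarray:
    """Area centroid of the enclosed region (not the vertex mean).

    Uses the shoelace/Green's-theorem centroid, so the result is independent
    of how densely the boundary is sampled.
    """
    poly = outline.polygon
    if poly.area <= 1e-12:
        raise DegenerateOutline("outline encloses (near-)zero area")
    c = poly.centroid
    return np.array([c.x, c.y])


def _line_polygon_intersections(
    point: np.ndarray, direction: np.ndarray, vertices: np.ndarray
) -> np.ndarray:
    """All intersections of an infinite line with a closed polygon boundary.

    Returns an (m, 2) array of intersection points (may be empty).
    """
    p, q = vertices, np.roll(vertices, -1, axis=0)
    edge = q - p
    # solve point + t*direction = p + w*edge
    denom = direction[0] * edge[:, 1] - direction[1] * edge[:, 0]
    ok = np.abs(denom) > 1e-15
    rel = p - point
    w = np.where(ok, (rel[:, 0] * direction[1] - rel[:, 1] * direction[0]) / np.where(ok, denom, 1.0), np.nan)
    # small tolerance so a crossing exactly through a vertex is not lost to
    # rounding on both adjacent edges
    hit = ok & (w >= -1e-9) & (w < 1.0 + 1e-9)
    pts = p[hit] + np.clip(w[hit, None], 0.0, 1.0) * edge[hit]
    if len(pts) > 1:  # drop vertex-hit duplicates
        keep = [0]
        for i in range(1, len(pts)):
            if np.min(np.linalg.norm(pts[i] - pts[keep], axis=1)) > 1e-6:
                keep.append(i)
        pts = pts[keep]
    return pts


def locate_start(outline: Outline, landmarks: LandmarkSet) -> CurveFrame:
    """Find the occipital start point and sweep orientation.

    The exocanthia are projected along the plane normal into the outline
    plane; the perpendicular bisector of the projected ex-ex segment is
    intersected with the outline and the posterior crossing -- the one
    farther from the ex midpoint, i.e. on the occiput opposite the eyes --
    is the start.
    """
    center = area_centroid(outline)
    if not outline.polygon.contains(Point(center)):
        raise StartNotFound("outline centroid lies outside the polygon")

    ex_l = to_plane_coords(landmarks.ex_left, outline.plane)
    ex_r = to_plane_coords(landmarks.ex_right, outline.plane)
    if np.linalg.norm(ex_r - ex_l) <= 1e-9:
        raise StartNotFound("projected exocanthia coincide")
    mid = 0.5 * (ex_l + ex_r)
    seg = ex_r - ex_l
    perp = np.array([-seg[1], seg[0]]) / np.linalg.norm(seg)

    hits = _line_polygon_intersections(mid, perp, outline.vertices)
    if len(hits) == 0:
        raise StartNotFound("perpendicular bisector misses the outline")
    # posterior = the crossing farthest from the ex midpoint: the eyes sit
    # far anterior on the outline, so the occipital crossing is the distant
    # one.  (Distance, unlike a fixed axis, is invariant to in-plane rigid
    # motion of the whole configuration.)
    dists = np.linalg.norm(hits - mid, axis=1)
    start = hits[np.argmax(dists)]

    start_dir = start - center
    norm = np.linalg.norm(start_dir)
    if norm <= 1e-12:
        raise StartNotFound("start point coincides with the centroid")
    start_dir = start_dir / norm

    # sweep sign: the projected right exocanthion must fall in the first
    # half-turn from the start direction.
    rel_r = ex_r - center
    cross = start_dir[0] * rel_r[1] - start_dir[1] * rel_r[0]
    sign = 1 if cross > 0 else -1
    return CurveFrame(center=center, start_direction=start_dir, right_first_sign=sign, start_point=start)


def read_outline_csv(path, plane: CuttingPlane | None = None) -> Outline:
    """Read an outline polygon from CSV with columns u_mm,v_mm.

    ``plane`` defaults to the canonical z=0 plane (anterior +u), which is
    sufficient for the mesh-free entry point where the outline is already
    in plane coordinates.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if not {"u_mm", "v_mm"} <= set(df.columns):
        from .errors import InputError

        raise InputError(f"outline CSV {path} must have columns u_mm,v_mm")
    uv = df[["u_mm", "v_mm"]].to_numpy(dtype=float)
    if np.allclose(uv[0], uv[-1]):
        uv = uv[:-1]
    if plane is None:
        plane = CuttingPlane(
            origin=np.zeros(3),
            normal=np.array([0.0, 0.0, 1.0]),
            u_axis=np.array([1.0, 0.0, 0.0]),
            v_axis=np.array([0.0, 1.0, 0.0]),
        )
    if _loop_signed_area(uv) < 0:
        uv = uv[::-1]
    return Outline(vertices=uv, plane=plane)


def write_outline_csv(outline: Outline, path) -> None:
    import pandas as pd

    pd.DataFrame({"u_mm": outline.vertices[:, 0], "v_mm": outline.vertices[:, 1]}).to_csv(
        path, index=False
    )


def outline_is_simple(outline: Outline) -> bool:
    """True when the polygon boundary does not self-intersect."""
    return bool(shapely.is_simple(shapely.LinearRing(outline.vertices)))
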