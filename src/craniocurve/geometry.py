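"""Landmark-defined cutting planes.

The analysis plane is anchored on three external soft-tissue landmarks --
left and right exocanthion (outer eye corners) and one porion (upper margin
of the ear canal).  Those three points define a base plane; the skull
outline itself is taken on a parallel plane a configurable height above it
(40 mm by default), which clears the orbits while still crossing the vault.

All coordinates are in millimetres.  A :class:`CuttingPlane` carries an
orthonormal in-plane frame (``u_axis`` anterior, ``v_axis`` completing a
right-handed triad with the superior normal) so downstream modules work in
plane-local 2-D coordinates.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import DegenerateLandmarks, InputError

__all__ = [
    "LandmarkSet",
    "CuttingPlane",
    "build_base_plane",
    "offset_plane",
    "to_plane_coords",
    "from_plane_coords",
    "read_landmarks",
]

#: Minimum triangle area (mm^2) below which the landmarks are treated as
#: collinear.
_MIN_TRIANGLE_AREA = 1e-6


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise InputError(f"non-finite landmark coordinate: {p!r}")
    return a


@dataclass(frozen=True)
class LandmarkSet:
    """The four external landmarks, as 3-D points in mm.

    ``po_right`` is optional: the plane needs only three points, and the
    right porion is used only for left-sided anterior plagiocephaly (the
    side unaffected by the deformity).
    """

    ex_left: np.ndarray
    ex_right: np.ndarray
    po_left: np.ndarray | None = None
    po_right: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "ex_left", _as_point(self.ex_left))
        object.__setattr__(self, "ex_right", _as_point(self.ex_right))
        for name in ("po_left", "po_right"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, _as_point(val))

    def porion(self, side: str) -> np.ndarray:
        """Return the porion on ``side`` ('left' or 'right')."""
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        p = self.po_left if side == "left" else self.po_right
        if p is None:
            raise InputError(f"porion on {side} side not provided")
        return p

    def transformed(self, matrix: np.ndarray) -> "LandmarkSet":
        """Apply a 4x4 homogeneous transform to every landmark."""
        m = np.asarray(matrix, dtype=float)

        def _tx(p):
            return None if p is None else (m[:3, :3] @ p + m[:3, 3])

        return LandmarkSet(
            ex_left=_tx(self.ex_left),
            ex_right=_tx(self.ex_right),
            po_left=_tx(self.po_left),
            po_right=_tx(self.po_right),
        )


@dataclass(frozen=True)
class CuttingPlane:
    """An oriented plane with an orthonormal in-plane frame.

    ``normal`` points superior (toward the head vertex); ``u_axis`` points
    anterior in-plane; ``v_axis = normal x u_axis`` so that
    ``u_axis x v_axis = normal``.
    """

    origin: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "normal", "u_axis", "v_axis"):
            object.__setattr__(self, name, _as_point(getattr(self, name)))

    def signed_distance(self, points) -> np.ndarray:
        """Signed distance of ``points`` (n,3) along the normal."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) @ self.normal


def build_base_plane(
    landmarks: LandmarkSet,
    side_of_porion: str = "left",
    superior_hint: np.ndarray | None = None,
) -> CuttingPlane:
    """Construct the base plane through both exocanthia and one porion.

    Parameters
    ----------
    landmarks
        The landmark set; the porion on ``side_of_porion`` is used.  The
        left porion is the default; the right is reserved for left-sided
        anterior plagiocephaly where the left side is deformed.
    superior_hint
        A point on the superior side of the plane (typically the mesh
        centroid); the normal is flipped to point toward it.  If ``None``
        the cross-product orientation is kept as computed.

    Raises
    ------
    DegenerateLandmarks
        If the three selected points span a triangle of area <= 1e-6 mm^2.
    """
    ex_l, ex_r = landmarks.ex_left, landmarks.ex_right
    po = landmarks.porion(side_of_porion)

    cross = np.cross(ex_r - ex_l, po - ex_l)
    area = 0.5 * np.linalg.norm(cross)
    if area <= _MIN_TRIANGLE_AREA:
        raise DegenerateLandmarks(
            f"plane landmarks are (near-)collinear: triangle area {area:.3g} mm^2"
        )
    normal = cross / np.linalg.norm(cross)

    origin = (ex_l + ex_r + po) / 3.0
    if superior_hint is not None:
        hint = _as_point(superior_hint)
        if (hint - origin) @ normal < 0:
            normal = -normal

    # Anterior axis: projection of (ex-midpoint - porion) into the plane.
    anterior = 0.5 * (ex_l + ex_r) - po
    anterior_in_plane = anterior - (anterior @ normal) * normal
    norm = np.linalg.norm(anterior_in_plane)
    if norm <= 1e-12:
        raise DegenerateLandmarks("anterior direction degenerate in plane")
    u_axis = anterior_in_plane / norm
    v_axis = np.cross(normal, u_axis)
    return CuttingPlane(origin=origin, normal=normal, u_axis=u_axis, v_axis=v_axis)


def offset_plane(plane: CuttingPlane, height: float) -> CuttingPlane:
    """Return a parallel plane displaced ``height`` mm along the normal.

    The default analysis height in the pipeline is 40 mm (4 cm above the
    base plane); axes are unchanged.
    """
    if not np.isfinite(height):
        raise ValueError("height must be finite")
    return replace(plane, origin=plane.origin + float(height) * plane.normal)


def to_plane_coords(points, plane: CuttingPlane) -> np.ndarray:
    """Project 3-D points into plane-local (u, v) mm coordinates.

    The out-of-plane component is dropped, i.e. points are projected along
    the plane normal.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    rel = pts - plane.origin
    uv = np.column_stack([rel @ plane.u_axis, rel @ plane.v_axis])
    return uv[0] if single else uv


def from_plane_coords(uv, plane: CuttingPlane) -> np.ndarray:
    """Inverse of :func:`to_plane_coords` for in-plane points."""
    arr = np.asarray(uv, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    pts = plane.origin + np.outer(arr[:, 0], plane.u_axis) + np.outer(arr[:, 1], plane.v_axis)
    return pts[0] if single else pts


_LANDMARK_ALIASES = {
    "ex_left": "ex_left",
    "ex_l": "ex_left",
    "exocanthion_left": "ex_left",
    "ex_right": "ex_right",
    "ex_r": "ex_right",
    "exocanthion_right": "ex_right",
    "po_left": "po_left",
    "po_l": "po_left",
    "porion_left": "po_left",
    "po_right": "po_right",
    "po_r": "po_right",
    "porion_right": "po_right",
}


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark file (JSON mapping or CSV with name,x,y,z), units mm.

    Names are case-insensitive; ``ex_l``/``exocanthion_left`` style aliases
    are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"landmark file not found: {path}")
    found: dict[str, np.ndarray] = {}
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
            items = data.items()
        else:
            with open(path, newline="") as fh:
                reader = csv.reader(fh)
                rows = [r for r in reader if r and r[0].strip()]
            if rows and rows[0][0].strip().lower() in ("name", "landmark"):
                rows = rows[1:]
            items = [(r[0], [float(r[1]), float(r[2]), float(r[3])]) for r in rows]
        for name, xyz in items:
            key = _LANDMARK_ALIASES.get(str(name).strip().lower())
            if key is not None:
                found[key] = _as_point(xyz)
    except (ValueError, IndexError, json.JSONDecodeError) as exc:
        raise InputError(f"malformed landmark file {path}: {exc}") from exc
    missing = {"ex_left", "ex_right"} - set(found)
    if missing or ("po_left" not in found and "po_right" not in found):
        raise InputError(
            f"landmark file {path} missing required landmarks "
            f"(need ex_left, ex_right and at least one porion)"
        )
    return LandmarkSet(**found)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set as JSON (mm)."""
    data = {}
    for name in ("ex_left", "ex_right", "po_left", "po_right"):
        p = getattr(landmarks, name)
        if p is not None:
            data[name] = [float(x) for x in p]
    Path(path).write_text(json.dumps(data, indent=2))
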