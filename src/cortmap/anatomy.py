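"""Anatomical tibial coordinate system.

The frame is built from diaphyseal geometry plus digitized landmarks:

1. a *temporal* z-axis joins the centres of least-squares circles fitted to the
   cortex cross-sections in two transverse planes of the diaphysis (oriented
   superiorly);
2. the y-axis is the PCL-attachment -> medial-tuberosity-edge line, projected
   orthogonal to the temporal z (positive anterior);
3. x = y x z_temporal (positive right) and the true z = x x y, which equals the
   temporal z exactly because y was orthogonalized first.  The triad is
   right-handed (x x y = z) by construction.
4. the origin is the intersection of the true z-axis with the distal articular
   surface patch.

The source description chains two cross products whose literal order gives a
negated x with z superior and y anterior; the construction above is the
canonical right-handed resolution and is flagged in the methods note for
anyone comparing frames with other software.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TibialCS",
    "Landmarks",
    "fit_section_circle",
    "build_tibial_cs",
    "to_cs",
    "from_cs",
]


@dataclass
class TibialCS:
    """Origin plus orthonormal right-handed axes (x right, y anterior, z superior)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        for name in ("x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"{name} is zero")
            setattr(self, name, v / n)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("axes are not orthonormal")
        if np.dot(np.cross(self.x_axis, self.y_axis), self.z_axis) < 0:
            raise ValueError("axes are not right-handed (x cross y must equal z)")

    @property
    def rotation(self) -> np.ndarray:
        """Columns are the frame axes expressed in world coordinates."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.rotation
        return out[0] if np.ndim(points) == 1 else out

    def to_world(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.rotation.T + self.origin
        return out[0] if np.ndim(points) == 1 else out

    def direction_to_local(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) @ self.rotation

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous local->world transform."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.origin
        return M

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix.tolist()}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TibialCS":
        with open(path) as fh:
            M = np.asarray(json.load(fh)["matrix"])
        return cls(M[:3, 3], M[:3, 0], M[:3, 1], M[:3, 2])

    @classmethod
    def identity(cls) -> "TibialCS":
        return cls(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1])


@dataclass
class Landmarks:
    """Digitized tibial landmarks (world mm) plus the distal articular patch."""

    pcl_attachment: np.ndarray
    tuberosity_medial_edge: np.ndarray
    eminence_medial: np.ndarray
    eminence_lateral: np.ndarray
    talar_dome_medial: np.ndarray
    talar_dome_lateral: np.ndarray
    distal_articular_surface: object = None  # trimesh.Trimesh patch
    extra: dict = field(default_factory=dict)

    _POINTS = (
        "pcl_attachment",
        "tuberosity_medial_edge",
        "eminence_medial",
        "eminence_lateral",
        "talar_dome_medial",
        "talar_dome_lateral",
    )

    def __post_init__(self) -> None:
        for name in self._POINTS:
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name} must be a finite 3-vector")
            setattr(self, name, p)
        if np.allclose(self.eminence_medial, self.eminence_lateral):
            raise ValueError("eminence points must be distinct")
        if np.allclose(self.talar_dome_medial, self.talar_dome_lateral):
            raise ValueError("talar dome points must be distinct")

    @property
    def eminence_midpoint(self) -> np.ndarray:
        return 0.5 * (self.eminence_medial + self.eminence_lateral)

    @property
    def talar_midpoint(self) -> np.ndarray:
        return 0.5 * (self.talar_dome_medial + self.talar_dome_lateral)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: getattr(self, k).tolist() for k in self._POINTS}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str, distal_patch=None) -> "Landmarks":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**{k: np.asarray(d[k]) for k in cls._POINTS},
                   distal_articular_surface=distal_patch)


def fit_section_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares circle through 2D points.

    Returns ``(center, radius, rms_residual)``.  Uses the Kasa linearisation:
    minimise ``sum((x-a)^2 + (y-b)^2 - r^2)^2`` which is linear in
    ``(a, b, r^2 - a^2 - b^2)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    if np.linalg.matrix_rank(A - A.mean(axis=0)) < 2:
        raise ValueError("points are collinear; circle fit is degenerate")
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]
    radius = float(np.sqrt(sol[2] + center @ center))
    resid = float(np.sqrt(np.mean((np.hypot(x - center[0], y - center[1]) - radius) ** 2)))
    return center, radius, resid


def _section_points(mesh, z_value: float, axis: np.ndarray, origin: np.ndarray,
                    slab: float = 2.5):
    """Surface points within a thin slab around the transverse plane.

    Uses mesh vertices directly (rather than a mesh/plane intersection) so the
    extraction is exactly equivariant under rigid motion of the inputs.
    """
    verts = mesh.vertices if hasattr(mesh, "vertices") else np.asarray(mesh)
    offs = (verts - origin) @ axis
    sel = np.abs(offs - z_value) <= slab
    if np.sum(sel) < 8:
        raise ValueError(f"section plane at offset {z_value:.1f} mm misses the mesh")
    return verts[sel]


def build_tibial_cs(mesh, landmarks: Landmarks,
                    plane_fractions: tuple[float, float] = (0.3, 0.7)) -> TibialCS:
    """Construct the anatomical tibial frame from a surface mesh and landmarks.

    ``plane_fractions`` place the two transverse circle-fitting planes along the
    tibial length (eminence-midpoint to talar-midpoint), defaulting to the
    diaphysis limits 30% and 70%.
    """
    sup = landmarks.eminence_midpoint - landmarks.talar_midpoint
    L = np.linalg.norm(sup)
    if L == 0:
        raise ValueError("eminence and talar midpoints coincide")
    axis0 = sup / L  # provisional superior direction for sectioning

    centers = []
    for frac in plane_fractions:
        pts3 = _section_points(mesh, frac * L, axis0, landmarks.talar_midpoint)
        # project into an in-plane 2D basis
        e1 = np.cross(axis0, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(axis0, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis0, e1)
        uv = np.column_stack([(pts3 - landmarks.talar_midpoint) @ e1,
                              (pts3 - landmarks.talar_midpoint) @ e2])
        c2d, _, _ = fit_section_circle(uv)
        offset = ((pts3 - landmarks.talar_midpoint) @ axis0).mean()  # = frac * L
        centers.append(landmarks.talar_midpoint + c2d[0] * e1 + c2d[1] * e2
                       + offset * axis0)
    c_lo, c_hi = centers
    tz = c_hi - c_lo
    if np.linalg.norm(tz) == 0:
        raise ValueError("section circle centres coincide; temporal z undefined")
    tz = tz / np.linalg.norm(tz)
    if np.dot(tz, axis0) < 0:  # orient superior
        tz = -tz

    y_raw = landmarks.tuberosity_medial_edge - landmarks.pcl_attachment
    if np.linalg.norm(y_raw) == 0:
        raise ValueError("pcl_attachment equals tuberosity_medial_edge; y-axis degenerate")
    y = y_raw - np.dot(y_raw, tz) * tz
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("y-axis is parallel to the temporal z-axis")
    y /= ny

    x = np.cross(y, tz)  # positive right with y anterior, z superior
    x /= np.linalg.norm(x)
    z = np.cross(x, y)  # true z, positive superior; equals tz exactly

    origin = _intersect_z_axis_with_patch(landmarks, c_lo, z)
    return TibialCS(origin, x, y, z)


def _intersect_z_axis_with_patch(landmarks: Landmarks, shaft_point: np.ndarray,
                                 z: np.ndarray) -> np.ndarray:
    patch = landmarks.distal_articular_surface
    if patch is None:
        # no patch digitized: drop to the talar-midpoint level along z
        t = np.dot(landmarks.talar_midpoint - shaft_point, z)
        return shaft_point + t * z
    locs = _line_triangles_intersections(shaft_point, z, np.asarray(patch.triangles))
    if len(locs) == 0:
        raise ValueError("true z-axis does not intersect the distal articular surface")
    # most distal intersection
    return locs[np.argmin(locs @ z)]


def _line_triangles_intersections(point: np.ndarray, direction: np.ndarray,
                                  triangles: np.ndarray) -> np.ndarray:
    """All intersections of an infinite line with a triangle soup (Moller-Trumbore)."""
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(np.broadcast_to(direction, e2.shape), e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    hits = []
    if not np.any(ok):
        return np.empty((0, 3))
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = point - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", e2, q)
    inside = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9)
    for ti in t[inside]:
        hits.append(point + ti * direction)
    return np.asarray(hits) if hits else np.empty((0, 3))


def to_cs(points: np.ndarray, cs: TibialCS) -> np.ndarray:
    """World -> frame coordinates (rigid transform; round-trips with from_cs)."""
    return cs.to_local(points)


def from_cs(points: np.ndarray, cs: TibialCS) -> np.ndarray:
    return cs.to_world(points)
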