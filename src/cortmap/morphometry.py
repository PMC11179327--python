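"""Femorotibial angle and medial-plateau coronal inclination.

The anatomical axis of each bone is a total-least-squares line through the
area centroids of equally spaced diaphyseal cross-sections (10 for the femur,
12 for the tibia).  The FTA is the angle between the two axes projected onto
the coronal (xz) plane of the femoral frame, anchored at 180 degrees for a
straight limb; values above 180 mean varus (the distal tibia deviates toward
the midline relative to the prolonged femoral axis).

The medial tibial plateau (MCT) is summarized by its orthogonal least-squares
plane; the coronal inclination is the minimum angle between the tibial x-axis
and the line where the plateau plane crosses the tibial xz-plane.  For a plane
``z = c + b x`` in the tibial frame this is exactly ``arctan |b|``; any
sagittal tilt leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .anatomy import TibialCS

__all__ = [
    "AnatomicalAxis",
    "FTAResult",
    "MCTPlane",
    "compute_section_centroids",
    "fit_anatomical_axis",
    "compute_fta",
    "fit_mct_plane",
    "mct_coronal_angle",
]

N_PLANES = {"femur": 10, "tibia": 12}  # diaphysis into 11 / 13 equal sections


@dataclass
class AnatomicalAxis:
    """Total-least-squares 3D line through cross-section centroids."""

    point: np.ndarray
    direction: np.ndarray
    rms_residual: float
    n_centroids: int


@dataclass
class FTAResult:
    fta: float

    def __post_init__(self) -> None:
        if not 90.0 < self.fta < 270.0:
            raise ValueError("FTA outside the plausible (90, 270) degree range")

    @property
    def varus_deviation(self) -> float:
        return self.fta - 180.0


@dataclass
class MCTPlane:
    """Orthogonal least-squares plane through digitized plateau points."""

    normal: np.ndarray
    offset: float           # plane: normal . p = offset
    fit_rms: float
    centroid: np.ndarray


def compute_section_centroids(mesh, frame: TibialCS, bone: str,
                              band: tuple[float, float] = (0.3, 0.7)) -> np.ndarray:
    """Area centroids of equally spaced diaphyseal cross-sections (world mm).

    The diaphysis is the ``band`` fraction of the mesh's z-extent in ``frame``;
    it is divided into n+1 equal sections by n interior planes perpendicular
    to the frame z-axis (n = 10 femur, 12 tibia).
    """
    if bone not in N_PLANES:
        raise ValueError("bone must be 'femur' or 'tibia'")
    n = N_PLANES[bone]
    tm = mesh.as_trimesh() if hasattr(mesh, "as_trimesh") else mesh
    z_local = frame.to_local(tm.vertices)[:, 2]
    z0, z1 = z_local.min(), z_local.max()
    lo = z0 + band[0] * (z1 - z0)
    hi = z0 + band[1] * (z1 - z0)
    centroids = []
    for i in range(1, n + 1):
        z = lo + i * (hi - lo) / (n + 1)
        origin = frame.to_world(np.array([0.0, 0.0, z]))
        sec = tm.section(plane_origin=origin, plane_normal=frame.z_axis)
        if sec is None:
            raise ValueError(f"section plane {i} at z={z:.1f} mm misses the mesh")
        loops = sec.discrete
        pts = max(loops, key=lambda a: len(a))
        local = frame.to_local(pts)
        poly = Polygon(local[:, :2])
        c = poly.centroid
        centroids.append(frame.to_world(np.array([c.x, c.y, local[:, 2].mean()])))
    return np.asarray(centroids)


def fit_anatomical_axis(centroids: np.ndarray) -> AnatomicalAxis:
    """First principal direction through the centroid mean (orthogonal LSQ line)."""
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least 2 centroids")
    mean = pts.mean(axis=0)
    d = pts - mean
    if np.allclose(d, 0):
        raise ValueError("all centroids coincide; axis undefined")
    _, s, vt = np.linalg.svd(d, full_matrices=False)
    direction = vt[0]
    resid = d - np.outer(d @ direction, direction)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AnatomicalAxis(point=mean, direction=direction, rms_residual=rms,
                          n_centroids=len(pts))


def compute_fta(femoral_axis: AnatomicalAxis, tibial_axis: AnatomicalAxis,
                femoral_frame: TibialCS, side: str = "right") -> FTAResult:
    """Coronal-plane femorotibial angle in the femoral frame.

    Both axis directions are projected onto the femoral xz-plane, the femoral
    direction oriented distally (hip to knee) and the tibial direction
    distally (knee to ankle).  The signed deviation of the tibial direction
    from the prolonged femoral axis, positive toward the midline (varus), is
    added to the 180-degree anchor of a straight limb.
    """
    f = femoral_frame.direction_to_local(femoral_axis.direction)
    t = femoral_frame.direction_to_local(tibial_axis.direction)
    if f[2] > 0:
        f = -f  # distal = inferior
    if t[2] > 0:
        t = -t
    f2 = np.array([f[0], f[2]])
    t2 = np.array([t[0], t[2]])
    if np.linalg.norm(f2) < 1e-9 or np.linalg.norm(t2) < 1e-9:
        raise ValueError("axis is orthogonal to the coronal plane; FTA undefined")
    delta = np.arctan2(f2[0] * t2[1] - f2[1] * t2[0], f2 @ t2)
    medial_sign = -1.0 if side == "right" else 1.0
    varus = medial_sign * np.degrees(delta)
    return FTAResult(fta=180.0 + varus)


def fit_mct_plane(points: np.ndarray) -> MCTPlane:
    """Orthogonal least-squares plane (smallest principal component) through points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need at least 3 plateau points")
    mean = pts.mean(axis=0)
    d = pts - mean
    _, s, vt = np.linalg.svd(d, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("plateau points are collinear; plane undefined")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal  # orient superior
    rms = float(np.sqrt(np.mean((d @ normal) ** 2)))
    return MCTPlane(normal=normal, offset=float(normal @ mean), fit_rms=rms,
                    centroid=mean)


def mct_coronal_angle(plane: MCTPlane, tibial_cs: TibialCS) -> float:
    """Minimum angle between the tibial x-axis and the plateau/xz-plane crossing line.

    The crossing line of the plateau plane with the tibial coronal (xz) plane
    has direction ``n_plateau x y_hat`` in frame coordinates; the result is the
    acute angle (degrees) between that line and the x-axis.  A horizontal
    plateau gives 0; ``z = c + b x`` gives ``arctan |b|``.
    """
    n_local = tibial_cs.direction_to_local(plane.normal)
    line = np.cross(n_local, [0.0, 1.0, 0.0])
    norm = np.linalg.norm(line)
    if norm < 1e-12:
        raise ValueError("plateau plane is parallel to the xz-plane normal; "
                         "no unique crossing line")
    cosang = abs(line[0]) / norm
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
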