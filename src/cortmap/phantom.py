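"""Synthetic tibia phantom: CT volumes, meshes, landmarks and line profiles.

The phantom is a tapered tube of cortical bone (density ``y1``) around a
trabecular core (``y2``) embedded in soft tissue (``y0``), imaged by an
isotropic Gaussian point-spread function of width ``psf_sigma`` and corrupted
by i.i.d. Gaussian noise — the same three-level blurred-edge model that the
thickness estimator fits, so every downstream stage has an exact ground truth.

Geometry conventions: the bone axis runs along world +z from the distal end
(z=0) to the proximal end (z=tibial_length); x is positive right, y positive
anterior.  For a right tibia the medial side is -x, for a left tibia +x.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr

from .anatomy import Landmarks, TibialCS
from .volume import CTVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_tibia_phantom",
    "generate_line_profile",
    "generate_mct_points",
    "generate_alignment_meshes",
    "blurred_profile",
]


def default_radius_profile(h):
    """Outer cortex radius (mm) vs height fraction: mild flare at both ends."""
    h = np.asarray(h, dtype=float)
    return 13.0 + 3.0 * (2.0 * h - 1.0) ** 2


def uniform_thickness(value: float) -> Callable:
    def t(h, azimuth):
        return np.broadcast_to(np.float64(value), np.broadcast_shapes(
            np.shape(h), np.shape(azimuth))).copy()
    return t


def medial_lateral_thickness(medial: float, lateral: float, side: str = "right",
                             sharpness: float = 3.0) -> Callable:
    """Thickness close to ``medial`` on the medial half and ``lateral`` opposite.

    Azimuth 0 is +x; medial is -x for a right tibia, +x for a left one.  The
    transition is a smooth tanh ramp so the half-shells are near-constant while
    the field stays differentiable (the blur model needs no sharp seams).
    """
    sign = -1.0 if side == "right" else 1.0

    def t(h, azimuth):
        med_weight = 0.5 * (1.0 + np.tanh(sharpness * sign * np.cos(azimuth)))
        return lateral + (medial - lateral) * med_weight
    return t


@dataclass
class PhantomSpec:
    """Ground-truth description of the synthetic tibia and its imaging."""

    tibial_length: float = 330.0                     # mm, eminence to talar midpoints
    shaft_outer_radius_profile: Callable = default_radius_profile
    thickness_field: Callable = field(default_factory=lambda: uniform_thickness(5.0))
    densities: tuple[float, float, float] = (0.0, 1200.0, 300.0)  # y0, y1, y2 HU
    psf_sigma: float = 0.9                           # mm
    voxel_spacing: tuple[float, float, float] = (0.7, 0.7, 1.0)
    noise_sd: float = 15.0                           # HU
    varus_angle: float = 0.0                         # deg, femoral coronal deviation
    mct_coronal_slope: float = float(np.tan(np.radians(12.2)))
    side: str = "right"
    seed: int = 0

    def validate(self) -> None:
        if self.tibial_length <= 0:
            raise ValueError("tibial_length must be positive")
        y0, y1, y2 = self.densities
        if not (y1 > y2 > y0):
            raise ValueError("densities must satisfy y1 > y2 > y0 (cortex densest)")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing entries must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        hh, aa = np.meshgrid(np.linspace(0, 1, 41), np.linspace(-np.pi, np.pi, 37))
        t = np.asarray(self.thickness_field(hh, aa), dtype=float)
        if np.any(t <= 0.5) or np.any(t >= 12.0):
            raise ValueError("thickness_field values must lie in (0.5, 12) mm everywhere")
        r = np.asarray(self.shaft_outer_radius_profile(np.linspace(0, 1, 41)), dtype=float)
        if np.any(r - t.max() <= 0.5):
            raise ValueError("shaft_outer_radius_profile leaves no medullary core")

    @property
    def medial_sign(self) -> float:
        return -1.0 if self.side == "right" else 1.0


@dataclass
class GroundTruth:
    """Everything the phantom knows: the oracle for every downstream stage."""

    spec: PhantomSpec
    landmarks: Landmarks
    true_tibial_cs: TibialCS
    true_fta: float
    true_mct_angle: float

    def true_thickness_at(self, points: np.ndarray) -> np.ndarray:
        """Ground-truth cortical thickness (mm) at world points on the surface."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = pts[:, 2] / self.spec.tibial_length
        az = np.arctan2(pts[:, 1], pts[:, 0])
        t = np.asarray(self.spec.thickness_field(h, az), dtype=float)
        return t[0] if np.ndim(points) == 1 else t

    def height_fraction(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts[:, 2] / self.spec.tibial_length


def blurred_profile(x, x0, t, sigma, densities):
    """Closed-form blurred two-edge line profile.

    ``y(x) = y0 + (y1-y0) Phi((x-x0)/sigma) + (y2-y1) Phi((x-x0-t)/sigma)``
    with x in mm along the inward normal (negative = outside the bone).
    """
    y0, y1, y2 = densities
    x = np.asarray(x, dtype=float)
    return y0 + (y1 - y0) * ndtr((x - x0) / sigma) + (y2 - y1) * ndtr((x - x0 - t) / sigma)


def generate_line_profile(t, x0, densities, sigma, spacing, half_length,
                          noise_sd=0.0, seed=None, rng=None):
    """Sample a noisy blurred cortical line profile on a regular offset grid.

    Returns ``(x, values)`` with x from -half_length to +half_length in steps
    of ``spacing``; x=0 is the nominal surface crossing, positive x inward.
    """
    if t <= 0:
        raise ValueError("thickness t must be > 0")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if half_length < x0 + t + 3.0 * sigma:
        raise ValueError("half_length too short to contain both cortical edges")
    x = np.arange(-half_length, half_length + spacing / 2, spacing)
    y = blurred_profile(x, x0, t, sigma, densities)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    return x, y


def generate_mct_points(coronal_slope, sagittal_slope=0.0, n=8, noise_sd=0.0,
                        seed=None, offset=0.0, side="right"):
    """Scatter n points on the medial-plateau footprint of a tilted plane.

    The plane is ``z = offset + coronal_slope * x + sagittal_slope * y`` in the
    tibial frame; noise perturbs z only (digitization error).  The footprint
    spans the medial compartment: 5-35 mm from the midline mediolaterally and
    +/-20 mm anteroposteriorly, the scale of an adult medial plateau.
    """
    if n < 3:
        raise ValueError("need at least 3 plateau points")
    rng = np.random.default_rng(seed)
    sign = -1.0 if side == "right" else 1.0
    x = sign * rng.uniform(5.0, 35.0, n)
    y = rng.uniform(-20.0, 20.0, n)
    z = offset + coronal_slope * x + sagittal_slope * y
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, n)
    return np.column_stack([x, y, z])


def _tube_mesh(axis_point, axis_dir, length, radius_fn, n_rings=40, n_theta=48):
    """Open tube mesh along an axis; radius_fn maps [0,1] along-length fraction to mm."""
    d = np.asarray(axis_dir, dtype=float)
    d /= np.linalg.norm(d)
    e1 = np.cross(d, [0, 0, 1.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(d, [0, 1.0, 0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    fracs = np.linspace(0, 1, n_rings)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    verts = []
    for f in fracs:
        r = float(radius_fn(f))
        c = np.asarray(axis_point) + f * length * d
        ring = c + r * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
        verts.append(ring)
    verts = np.vstack(verts)
    faces = []
    for k in range(n_rings - 1):
        a = k * n_theta
        b = (k + 1) * n_theta
        for i in range(n_theta):
            j = (i + 1) % n_theta
            faces.append([a + i, b + i, b + j])
            faces.append([a + i, b + j, a + j])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def _distal_patch(radius=11.0, z=0.0, n=24):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    verts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                             np.full(n, z)])
    verts = np.vstack([[0.0, 0.0, z], verts])
    faces = [[0, 1 + i, 1 + (i + 1) % n] for i in range(n)]
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)


def default_landmarks(spec: PhantomSpec) -> Landmarks:
    L = spec.tibial_length
    m = spec.medial_sign
    return Landmarks(
        pcl_attachment=np.array([0.0, -12.0, L - 8.0]),
        tuberosity_medial_edge=np.array([0.0, 14.0, L - 45.0]),
        eminence_medial=np.array([9.0 * m, 0.0, L]),
        eminence_lateral=np.array([-9.0 * m, 0.0, L]),
        talar_dome_medial=np.array([8.0 * m, 0.0, 0.0]),
        talar_dome_lateral=np.array([-8.0 * m, 0.0, 0.0]),
        distal_articular_surface=_distal_patch(z=0.0),
    )


def generate_tibia_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Render the three-density tube, blur with the PSF, add noise.

    Identical specs (same seed) produce bit-identical volumes.
    """
    spec.validate()
    sx, sy, sz = spec.voxel_spacing
    L = spec.tibial_length
    r_max = float(np.max(spec.shaft_outer_radius_profile(np.linspace(0, 1, 41))))
    half = r_max + 6.0
    nx = int(np.ceil(2 * half / sx)) + 1
    ny = int(np.ceil(2 * half / sy)) + 1
    z_lo, z_hi = -2.0 * sz, L + 2.0 * sz
    nz = int(np.ceil((z_hi - z_lo) / sz)) + 1
    origin = (-half, -half, z_lo)

    xs = origin[0] + sx * np.arange(nx)
    ys = origin[1] + sy * np.arange(ny)
    zs = origin[2] + sz * np.arange(nz)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    H = (zs / L)[None, None, :]

    r_xy = np.hypot(X, Y)
    az = np.arctan2(Y, X)
    h_c = np.clip(H, 0.0, 1.0)
    r_out = np.asarray(spec.shaft_outer_radius_profile(h_c), dtype=float)
    thick = np.asarray(spec.thickness_field(h_c, az), dtype=float)
    in_z = (H >= 0.0) & (H <= 1.0)

    y0, y1, y2 = spec.densities
    vol = np.full((nx, ny, nz), y0, dtype=np.float32)
    cortex = in_z & (r_xy <= r_out) & (r_xy > r_out - thick)
    core = in_z & (r_xy <= r_out - thick)
    vol[cortex] = y1
    vol[core] = y2

    sigma_vox = [spec.psf_sigma / s for s in spec.voxel_spacing]
    vol = gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape).astype(np.float32)

    volume = CTVolume(vol, spec.voxel_spacing, origin,
                      meta={"phantom_seed": spec.seed})
    lm = default_landmarks(spec)
    gt = GroundTruth(
        spec=dataclasses.replace(spec),
        landmarks=lm,
        true_tibial_cs=TibialCS.identity(),
        true_fta=180.0 + spec.varus_angle,
        true_mct_angle=float(np.degrees(np.arctan(spec.mct_coronal_slope))),
    )
    return volume, gt


def generate_alignment_meshes(spec: PhantomSpec, femur_length=380.0,
                              femur_radius=14.0):
    """Tibia and femur shaft meshes realizing the spec's varus angle.

    The tibia runs straight along +z.  The femur is hinged at the knee
    (0, 0, L) and tilted in the coronal plane so that the distal tibia deviates
    medially from the prolonged femoral axis by ``varus_angle`` degrees.
    Returns ``(femur_mesh, tibia_mesh, femoral_frame)``; the femoral frame is
    the identity (its coronal plane is the world xz-plane).
    """
    L = spec.tibial_length
    v = np.radians(spec.varus_angle)
    lat = -spec.medial_sign  # lateral direction sign on x
    # femoral axis, pointing distally (hip -> knee): knee is lateral of the hip
    f_dir = np.array([lat * np.sin(v), 0.0, -np.cos(v)])
    knee = np.array([0.0, 0.0, L])
    femur = _tube_mesh(knee, -f_dir, femur_length, lambda f: femur_radius)
    tibia = _tube_mesh([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], L,
                       spec.shaft_outer_radius_profile)
    return femur, tibia, TibialCS.identity()
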