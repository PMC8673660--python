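"""Conic/aspheric refracting surfaces, thick lens elements, and their
ray-optic (exact Snell) and wave-optic (thin-element OPD) realizations.

Sign conventions: light travels toward +z; a positive radius puts the center
of curvature on the +z side of the vertex; y is the decenter axis; tilt is a
right-handed rotation about the y axis through the lens center.  Decenter is
given in micrometres and tilt in degrees (the units of the misalignment
sweeps); everything else is millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_core import OPDMap

__all__ = [
    "ConicAsphericSurface",
    "LensElement",
    "sag",
    "sag_derivative",
    "surface_normal",
    "refract_direction",
    "intersect_surface",
    "element_opd_map",
    "interface_opd_map",
    "paraxial_power",
    "surface_power",
]

DECENTER_ENVELOPE_UM = 2000.0
TILT_ENVELOPE_DEG = 15.0


@dataclass
class ConicAsphericSurface:
    """Even-asphere surface: conic base plus a4*r^4 + a6*r^6.

    ``radius`` is the apex radius of curvature in mm (``inf`` or 0 for a
    plane); ``conic`` is the conic constant Q; ``a4``/``a6`` are in mm^-3 and
    mm^-5; ``semi_aperture`` is the clear semi-diameter in mm.
    """

    radius: float
    conic: float = 0.0
    a4: float = 0.0
    a6: float = 0.0
    semi_aperture: float = 10.0

    @property
    def curvature(self) -> float:
        if self.radius == 0 or not np.isfinite(self.radius):
            return 0.0
        return 1.0 / self.radius

    def max_valid_radius(self) -> float:
        c, Q = self.curvature, self.conic
        if c == 0 or (1 + Q) * c * c <= 0:
            return np.inf
        return 1.0 / np.sqrt((1 + Q) * c * c)


def sag(surface: ConicAsphericSurface, x, y):
    """Surface sag z(x, y) in mm.

    z = c r^2 / (1 + sqrt(1 - (1+Q) c^2 r^2)) + a4 r^4 + a6 r^6.
    Raises if any in-aperture point falls outside the conic domain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    c, Q = surface.curvature, surface.conic
    arg = 1.0 - (1 + Q) * c * c * r2
    inside = np.sqrt(r2) <= surface.semi_aperture
    if np.any(inside & (arg <= 0)):
        raise ValueError(
            "sag undefined: conic domain ends at r = "
            f"{surface.max_valid_radius():.4f} mm")
    arg = np.where(arg > 0, arg, 1.0)
    z = c * r2 / (1.0 + np.sqrt(arg)) + surface.a4 * r2 ** 2 + surface.a6 * r2 ** 3
    return z


def sag_derivative(surface: ConicAsphericSurface, x, y):
    """(dz/dx, dz/dy) of the sag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    c, Q = surface.curvature, surface.conic
    arg = np.maximum(1.0 - (1 + Q) * c * c * r2, 1e-12)
    s = np.sqrt(arg)
    # d/d(r2) of conic term: c/(1+s) + c r2 (1+Q) c^2 / (2 s (1+s)^2)
    dconic = c / (1 + s) + c * r2 * (1 + Q) * c * c / (2 * s * (1 + s) ** 2)
    dr2 = dconic + 2 * surface.a4 * r2 + 3 * surface.a6 * r2 ** 2
    return 2 * x * dr2, 2 * y * dr2


def surface_normal(surface: ConicAsphericSurface, x, y):
    """Unit normal with positive z component, shape (..., 3)."""
    dx, dy = sag_derivative(surface, x, y)
    n = np.stack(np.broadcast_arrays(-dx, -dy, np.ones_like(dx)), axis=-1)
    return n / np.linalg.norm(n, axis=-1, keepdims=True)


def refract_direction(d, normal, n1: float, n2: float):
    """Vector Snell refraction of unit direction(s) ``d`` at unit normal(s).

    Returns (d_refracted, tir_mask).  TIR rays keep their direction but are
    flagged.  The normal orientation is handled internally.
    """
    d = np.asarray(d, dtype=float)
    normal = np.asarray(normal, dtype=float)
    cosi = np.sum(d * normal, axis=-1, keepdims=True)
    nrm = np.where(cosi > 0, normal, -normal)   # normal along propagation
    cosi = np.abs(cosi)
    eta = n1 / n2
    sin2t = eta * eta * (1.0 - cosi * cosi)
    tir = sin2t[..., 0] > 1.0
    sin2t = np.minimum(sin2t, 1.0)
    cost = np.sqrt(1.0 - sin2t)
    dout = eta * d + (cost - eta * cosi) * nrm
    dout = dout / np.linalg.norm(dout, axis=-1, keepdims=True)
    dout = np.where(tir[..., np.newaxis], d, dout)
    return dout, tir


def intersect_surface(p, d, surface: ConicAsphericSurface, vertex_z: float,
                      max_iter: int = 30, tol: float = 1e-12):
    """Ray-surface intersection by Newton iteration (vectorized).

    ``p`` (..., 3) positions, ``d`` (..., 3) unit directions.  Returns
    (t, hit_mask): path length to the surface z = vertex_z + sag(x, y) and a
    mask of rays that intersect inside the clear semi-aperture.
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    t = (vertex_z - p[..., 2]) / d[..., 2]      # planar estimate
    ok = np.isfinite(t)
    for _ in range(max_iter):
        q = p + t[..., np.newaxis] * d
        r = np.hypot(q[..., 0], q[..., 1])
        rcap = surface.max_valid_radius() * 0.999999
        scalefac = np.where(r > rcap, rcap / np.maximum(r, 1e-300), 1.0)
        xs, ys = q[..., 0] * scalefac, q[..., 1] * scalefac
        big = ConicAsphericSurface(surface.radius, surface.conic, surface.a4,
                                   surface.a6, semi_aperture=np.inf)
        F = q[..., 2] - vertex_z - sag(big, xs, ys)
        gx, gy = sag_derivative(big, xs, ys)
        dF = d[..., 2] - gx * d[..., 0] - gy * d[..., 1]
        step = F / np.where(np.abs(dF) > 1e-14, dF, 1e-14)
        t = t - step
        if np.max(np.abs(step)) < tol:
            break
    q = p + t[..., np.newaxis] * d
    r = np.hypot(q[..., 0], q[..., 1])
    hit = ok & (r <= surface.semi_aperture) & (t > -1e9)
    return t, hit


@dataclass
class LensElement:
    """Thick lens with pose (decenter along y in um, tilt about y in degrees).

    ``axial_position`` is the bench-frame z of the front vertex for the
    un-posed lens; the pose rotates the lens rigidly about its center.
    """

    front: ConicAsphericSurface
    back: ConicAsphericSurface
    center_thickness: float
    material_index: float
    axial_position: float = 0.0
    decenter_y: float = 0.0      # micrometres
    tilt_y: float = 0.0          # degrees

    def __post_init__(self):
        if self.center_thickness <= 0:
            raise ValueError("center_thickness must be positive")
        if self.material_index < 1:
            raise ValueError("material_index must be >= 1")
        self.validate_pose()

    def validate_pose(self):
        if abs(self.decenter_y) > DECENTER_ENVELOPE_UM:
            raise ValueError(
                f"decenter {self.decenter_y} um outside the +-{DECENTER_ENVELOPE_UM:.0f} um "
                "validity envelope of the thin-element projection")
        if abs(self.tilt_y) > TILT_ENVELOPE_DEG:
            raise ValueError(
                f"tilt {self.tilt_y} deg outside the +-{TILT_ENVELOPE_DEG:.0f} deg "
                "validity envelope of the thin-element projection")

    @property
    def center_z(self) -> float:
        return self.axial_position + self.center_thickness / 2.0

    def pose_matrices(self):
        """(R, center): bench-frame rotation of the lens and its pivot point."""
        th = np.deg2rad(self.tilt_y)
        R = np.array([[np.cos(th), 0.0, np.sin(th)],
                      [0.0, 1.0, 0.0],
                      [-np.sin(th), 0.0, np.cos(th)]])
        center = np.array([0.0, self.decenter_y * 1e-3, self.center_z])
        return R, center

    def to_local(self, p):
        """Bench-frame points (..., 3) to lens-frame (origin at lens center)."""
        R, cen = self.pose_matrices()
        return (p - cen) @ R          # R^T applied from the left

    def to_bench(self, q):
        R, cen = self.pose_matrices()
        return q @ R.T + cen

    def local_direction(self, d):
        R, _ = self.pose_matrices()
        return np.asarray(d) @ R

    def bench_direction(self, d):
        R, _ = self.pose_matrices()
        return np.asarray(d) @ R.T


def surface_power(radius: float, n1: float, n2: float) -> float:
    """Refracting power of a single surface in diopters."""
    if radius == 0 or not np.isfinite(radius):
        return 0.0
    return (n2 - n1) / radius * 1000.0


def paraxial_power(element: LensElement, n_before: float, n_after: float) -> float:
    """Thick-lens (Gullstrand) paraxial power in diopters."""
    P1 = surface_power(element.front.radius, n_before, element.material_index)
    P2 = surface_power(element.back.radius, element.material_index, n_after)
    t_red = element.center_thickness / element.material_index * 1e-3  # metres
    return P1 + P2 - P1 * P2 * t_red


def interface_eikonal_profile(surface: ConicAsphericSurface, n1: float,
                              n2: float, r_max: float,
                              n_samples: int = 512):
    """Exact thin-screen profile of a refracting interface for collimated
    incidence: rays refract (vector Snell) at the true surface and are
    extrapolated back to the vertex plane, where the eikonal is recorded.

    Unlike the projection OPD -(n2-n1)*sag, this screen reproduces both the
    exact wavefront and the exact ray aim of the interface in the downstream
    homogeneous medium, which matters here because the corneal sag (>1 mm at
    the stop edge) is not small.  Returns (radii_at_vertex_plane, opd_um).
    """
    h = np.linspace(1e-9, r_max, n_samples)
    z = sag(surface, h, np.zeros_like(h))
    nrm = surface_normal(surface, h, np.zeros_like(h))
    d0 = np.zeros((n_samples, 3))
    d0[:, 2] = 1.0
    d1, _ = refract_direction(d0, nrm, n1, n2)
    # back-extrapolate the refracted ray to the vertex plane z=0
    x0 = h - z * d1[:, 0] / d1[:, 2]
    ell = z / d1[:, 2]                  # signed path, vertex plane -> surface
    w_mm = n1 * z - n2 * ell
    w_mm = w_mm - w_mm[0]
    order = np.argsort(x0)
    return x0[order], (w_mm * 1e3)[order]


def interface_opd_map(surface: ConicAsphericSurface, x, y,
                      n1: float, n2: float) -> np.ndarray:
    """Thin-screen OPD (um) of a single refracting interface, relative to the
    vertex: OPD(r) = -(n2 - n1) * sag(r).  Outside the semi-aperture -> NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(*np.broadcast_arrays(x, y))
    inside = r <= surface.semi_aperture
    big = ConicAsphericSurface(surface.radius, surface.conic, surface.a4,
                               surface.a6, semi_aperture=np.inf)
    rcap = min(big.max_valid_radius() * 0.999999, np.inf)
    scl = np.where(r > min(rcap, 1e300), rcap / np.maximum(r, 1e-300), 1.0)
    z = sag(big, x * scl, y * scl)
    opd_mm = -(n2 - n1) * z
    out = np.where(inside, opd_mm * 1e3, np.nan)
    return out


def element_opd_map(element: LensElement, x, y, n_before: float,
                    n_after: float, pitch: float | None = None,
                    incident_cone: float = 0.0) -> OPDMap:
    """Projected thin-element OPD map (um) of a posed thick lens.

    For each transverse sample a straight line through the posed lens volume
    is intersected with both surfaces; the OPD is the glass chord length
    times (n_glass - n_surround).  With ``incident_cone = 0`` the lines are
    z-parallel; a nonzero value is the reduced curvature (1/mm) of the
    illuminating converging cone, and the lines follow the local incident
    ray direction (important at this bench's ~11 deg marginal angles).
    Samples whose line misses the clear aperture are NaN (opaque).  Decenter
    acts as a transverse shift of the aligned map; tilt foreshortens and
    shears it (projection approximation).
    """
    element.validate_pose()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xx, yy = np.broadcast_arrays(x, y)
    shape = xx.shape
    t = element.center_thickness
    ng = element.material_index

    th = np.deg2rad(element.tilt_y)
    dy = element.decenter_y * 1e-3
    # line through (x, y) at the lens midplane, in the lens frame
    p0 = np.stack([xx, yy - dy, np.zeros(shape)], axis=-1)
    R, _ = element.pose_matrices()
    p0l = p0 @ R
    if incident_cone == 0.0:
        dl = np.broadcast_to(np.array([0.0, 0.0, 1.0]) @ R, shape + (3,))
    else:
        # local incident direction of the converging reference cone
        ux = -incident_cone * xx / n_before
        uy = -incident_cone * yy / n_before
        db = np.stack([ux, uy, np.ones(shape)], axis=-1)
        db = db / np.linalg.norm(db, axis=-1, keepdims=True)
        dl = db @ R

    def solve(surface, vertex_zl):
        big = ConicAsphericSurface(surface.radius, surface.conic, surface.a4,
                                   surface.a6, semi_aperture=np.inf)
        s = (vertex_zl - p0l[..., 2]) / dl[..., 2]
        rcap = big.max_valid_radius() * 0.999999
        for _ in range(40):
            q = p0l + s[..., np.newaxis] * dl
            r = np.hypot(q[..., 0], q[..., 1])
            scl = np.where(r > rcap, rcap / np.maximum(r, 1e-300), 1.0)
            qx, qy = q[..., 0] * scl, q[..., 1] * scl
            F = q[..., 2] - vertex_zl - sag(big, qx, qy)
            gx, gy = sag_derivative(big, qx, qy)
            dF = dl[..., 2] - gx * dl[..., 0] - gy * dl[..., 1]
            step = F / np.where(np.abs(dF) > 1e-14, dF, 1e-14)
            s = s - step
            if np.max(np.abs(step)) < 1e-12:
                break
        q = p0l + s[..., np.newaxis] * dl
        r = np.hypot(q[..., 0], q[..., 1])
        return s, r

    s_f, r_f = solve(element.front, -t / 2.0)
    s_b, r_b = solve(element.back, +t / 2.0)
    chord = s_b - s_f
    ap = min(element.front.semi_aperture, element.back.semi_aperture)
    valid = (r_f <= ap) & (r_b <= ap) & (chord > 0)
    n_surround = 0.5 * (n_before + n_after)
    opd_mm = (ng - n_surround) * chord
    opd = np.where(valid, opd_mm * 1e3, np.nan)
    if pitch is None:
        pitch = float(xx[0, 1] - xx[0, 0]) if shape[1] > 1 else 1.0
    # declared clear zone about the decentered center: geometric projected
    # aperture, further shrunk to the largest radius whose samples are all
    # defined (cone obliquity and tilt shear the footprint slightly)
    walk = 0.5 * t * (abs(incident_cone) * ap / n_before + abs(np.sin(th)))
    ap_proj = ap * np.cos(th) - abs(dy) * np.sin(abs(th)) - walk - 2 * pitch
    r_rel = np.hypot(xx, yy - dy)
    if np.any(~valid):
        r_clear = np.min(r_rel[~valid]) - pitch
        ap_proj = min(ap_proj, r_clear)
    return OPDMap(opd, pitch=pitch, aperture_diameter=2 * max(ap_proj, pitch),
                  center_y=dy)
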