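"""Geometric ray-tracing comparator engine.

Rays are traced exactly (vector Snell at conic/aspheric surfaces, rigid-body
pose of the IOL) through the bench; image quality is then evaluated in the
ZEMAX-style pupil-function convention: exit-pupil OPD against a reference
sphere, FFT/chirp-z of the pupil function for the PSF, and MTF from the PSF.
This keeps the comparator in the same Fourier-imaging convention as the field
engine, so differences between the two are physics (diffraction, coherent
fringes, projection-vs-exact treatment of tilt), not bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .field_core import OPDMap, pupil_to_focus
from .surfaces import (ConicAsphericSurface, LensElement, intersect_surface,
                       refract_direction, surface_normal)

__all__ = ["Ray", "RayBundle", "hexapolar_coordinates", "trace_bundle",
           "exit_pupil_opd", "psf_from_pupil", "ray_image_simulation"]


@dataclass
class Ray:
    """A single geometric ray: position (mm), unit direction, accumulated
    optical path length (mm), alive flag."""
    position: np.ndarray
    direction: np.ndarray
    opl: float = 0.0
    alive: bool = True


@dataclass
class RayBundle:
    """Vectorized collection of rays with their normalized launch coordinates."""
    positions: np.ndarray        # (N, 3) mm
    directions: np.ndarray       # (N, 3) unit
    opl: np.ndarray              # (N,) mm
    alive: np.ndarray            # (N,) bool
    pupil_coords: np.ndarray     # (N, 2) in the unit disk

    def __post_init__(self):
        norms = np.linalg.norm(self.directions, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("ray directions must be unit vectors")
        if np.any(np.hypot(self.pupil_coords[:, 0],
                           self.pupil_coords[:, 1]) > 1 + 1e-9):
            raise ValueError("pupil coordinates must lie in the unit disk")

    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive))


def hexapolar_coordinates(n_rings: int) -> np.ndarray:
    """Normalized hexapolar launch grid: ring k of n has 6k points."""
    if n_rings < 1:
        raise ValueError("n_rings >= 1")
    pts = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        rho = k / n_rings
        m = 6 * k
        ang = 2 * np.pi * np.arange(m) / m
        pts.extend(zip(rho * np.cos(ang), rho * np.sin(ang)))
    return np.asarray(pts)


def _launch(bench, n_rings: int, object_z: float | None = None) -> RayBundle:
    coords = hexapolar_coordinates(n_rings)
    R = bench.config.stop_diameter / 2.0
    N = len(coords)
    pos = np.zeros((N, 3))
    pos[:, 0] = coords[:, 0] * R
    pos[:, 1] = coords[:, 1] * R
    pos[:, 2] = bench.z_stop
    if object_z is None:
        dirs = np.tile([0.0, 0.0, 1.0], (N, 1))
        opl = np.zeros(N)
    else:
        # diverging pencil from the axial object point filling the stop
        src = np.array([0.0, 0.0, object_z])
        vec = pos - src
        dist = np.linalg.norm(vec, axis=1)
        dirs = vec / dist[:, None]
        opl = bench.config.n_air * dist
    return RayBundle(pos, dirs, opl, np.ones(N, bool), coords)


def _advance_to_plane(bundle, z, index):
    t = (z - bundle.positions[:, 2]) / bundle.directions[:, 2]
    bundle.positions = bundle.positions + t[:, None] * bundle.directions
    bundle.opl = bundle.opl + index * t


def _trace_interface(bundle, surface, vertex_z, n1, n2):
    t, hit = intersect_surface(bundle.positions, bundle.directions,
                               surface, vertex_z)
    bundle.positions = bundle.positions + t[:, None] * bundle.directions
    bundle.opl = bundle.opl + n1 * t
    q = bundle.positions
    nrm = surface_normal(surface, q[..., 0], q[..., 1])
    d2, tir = refract_direction(bundle.directions, nrm, n1, n2)
    bundle.directions = np.where((hit & ~tir)[:, None], d2, bundle.directions)
    bundle.alive = bundle.alive & hit & ~tir


def _trace_lens(bundle, element: LensElement, n_before, n_after):
    """Exact trace through a posed thick lens (work in the lens frame)."""
    p_l = element.to_local(bundle.positions)
    d_l = bundle.directions @ element.pose_matrices()[0]
    t = element.center_thickness
    for (surf, vz, na, nb) in ((element.front, -t / 2, n_before,
                                element.material_index),
                               (element.back, +t / 2,
                                element.material_index, n_after)):
        s, hit = intersect_surface(p_l, d_l, surf, vz)
        p_l = p_l + s[:, None] * d_l
        bundle.opl = bundle.opl + na * s
        nrm = surface_normal(surf, p_l[..., 0], p_l[..., 1])
        d2, tir = refract_direction(d_l, nrm, na, nb)
        d_l = np.where((hit & ~tir)[:, None], d2, d_l)
        bundle.alive = bundle.alive & hit & ~tir
    bundle.positions = element.to_bench(p_l)
    bundle.directions = d_l @ element.pose_matrices()[0].T


def _trace_ideal_lens(bundle, power_mm, z, index_before, index_after):
    """Paraxial-perfect thin phase element of reduced power (1/mm)."""
    _advance_to_plane(bundle, z, index_before)
    x, y = bundle.positions[:, 0], bundle.positions[:, 1]
    # reduced-slope kick and the matching OPL contribution -P r^2 / 2
    d = bundle.directions
    ured = d[:, :2] / d[:, 2:3] * index_before
    ured = ured - power_mm * bundle.positions[:, :2]
    uout = ured / index_after
    dz = 1.0 / np.sqrt(1.0 + np.sum(uout ** 2, axis=1))
    dnew = np.column_stack([uout * dz[:, None], dz])
    bundle.directions = dnew
    bundle.opl = bundle.opl - 0.5 * power_mm * (x * x + y * y)


def trace_bundle(bench, n_rings: int = 64,
                 object_z: float | None = None) -> RayBundle:
    """Trace a hexapolar bundle filling the stop to the bench's exit
    reference plane: collimated by default, or a diverging pencil from the
    axial object point at ``object_z`` (imaging conjugate).  Dead rays
    (missed aperture, TIR) stay flagged."""
    if n_rings < 4:
        raise ValueError("n_rings >= 4 for a usable pupil map")
    bundle = _launch(bench, n_rings, object_z)
    for op in bench.ray_train():
        kind = op[0]
        if kind == "interface":
            _, surf, vz, n1, n2 = op
            _trace_interface(bundle, surf, vz, n1, n2)
        elif kind == "lens":
            _, element, zfront, n1, n2 = op
            _trace_lens(bundle, element, n1, n2)
        elif kind == "ideal":
            _, P, z, n1, n2 = op
            _trace_ideal_lens(bundle, P, z, n1, n2)
        elif kind == "plane":
            _, z, n = op
            _advance_to_plane(bundle, z, n)
        else:  # pragma: no cover
            raise ValueError(f"unknown train op {kind}")
    if bundle.n_alive == 0:
        raise RuntimeError("all rays dead: bench geometry rejects the bundle")
    return bundle


def exit_pupil_opd(bundle: RayBundle, focus_point, focus_index: float,
                   grid_n: int = 128, pitch: float | None = None,
                   reference: str = "sphere",
                   min_alive_fraction: float = 0.9) -> OPDMap:
    """Exit-pupil OPD map (um) against a reference sphere about ``focus_point``.

    The bundle must have been traced to the exit reference plane.  OPD is
    reported as (chief OPL - ray OPL to the sphere), which makes the model
    cornea's spherical aberration positive.  ``reference='parabola'`` uses the
    paraxial quadratic instead of the exact sphere.  Samples outside the
    traced footprint are NaN; piston is removed.
    """
    alive = bundle.alive
    if alive.mean() < min_alive_fraction:
        raise RuntimeError(
            f"only {alive.mean():.0%} of rays alive; need >= "
            f"{min_alive_fraction:.0%} for a trustworthy pupil map")
    p = bundle.positions[alive]
    d = bundle.directions[alive]
    opl = bundle.opl[alive]
    c = np.asarray(focus_point, dtype=float)
    Rref = c[2] - np.median(p[:, 2])
    if reference == "sphere":
        dp = p - c
        b = np.sum(dp * d, axis=1)
        disc = b * b - (np.sum(dp * dp, axis=1) - Rref * Rref)
        t = -b - np.sqrt(np.maximum(disc, 0.0))
        total = opl + focus_index * t
    elif reference == "parabola":
        # OPL at the exit plane plus the paraxial converging quadratic
        # (a perfect paraxial beam has OPL(r) = const - n r^2/2R there)
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        total = opl + focus_index * r2 / (2.0 * Rref)
    else:
        raise ValueError("reference must be 'sphere' or 'parabola'")
    w = -(total - np.median(total))       # reference minus ray, mm
    if pitch is None:
        pitch = 2 * np.abs(p[:, :2]).max() / (grid_n - 4)
    interp = LinearNDInterpolator(p[:, :2], w * 1e3)  # um
    ax = (np.arange(grid_n) - grid_n // 2) * pitch
    xx, yy = np.meshgrid(ax, ax)
    vals = interp(xx, yy)
    foot = 2.0 * np.hypot(p[:, 0], p[:, 1]).max()
    # declared aperture: largest radius whose grid samples are all defined
    # (the hexapolar hull is a polygon slightly inside the footprint circle)
    rr = np.hypot(xx, yy)
    bad = ~np.isfinite(vals)
    r_ok = rr[bad].min() - pitch if bad.any() else np.inf
    return OPDMap(vals, pitch=pitch,
                  aperture_diameter=min(foot, 2.0 * r_ok))


def psf_from_pupil(opd: OPDMap, wavelength: float, zr: float,
                   output_pitch: float, output_shape: tuple[int, int],
                   output_center: tuple[float, float] = (0.0, 0.0),
                   defocus: float = 0.0,
                   normalize: bool = True) -> np.ndarray:
    """PSF = |chirp-z FT of the pupil function|^2.

    ``zr`` is the reduced pupil-to-focus distance (mm).  With
    ``normalize=True`` the result is scaled so the aberration-free PSF of the
    same pupil peaks at 1 (Strehl-style normalization).
    """
    A = np.where(np.isfinite(opd.opd), 1.0, 0.0)
    lam_um = wavelength * 1e-3
    # the map reports (reference - ray); the physical pupil phase is the ray
    # OPL excess, hence the minus sign
    phase = -np.where(np.isfinite(opd.opd), opd.opd, 0.0) / lam_um
    pupil = A * np.exp(2j * np.pi * phase)
    fld = pupil_to_focus(pupil, opd.pitch, wavelength, zr, output_pitch,
                         output_shape, output_center, defocus)
    psf = np.abs(fld) ** 2
    if normalize:
        ref = pupil_to_focus(A, opd.pitch, wavelength, zr, output_pitch,
                             (3, 3), (0.0, 0.0), 0.0)
        psf = psf / np.abs(ref[1, 1]) ** 2
    return psf


def ray_image_simulation(bench, target, psf: np.ndarray,
                         output_pitch: float, output_shape: tuple[int, int],
                         magnification: float,
                         output_center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Incoherent geometric image: demagnified ideal target convolved with
    the ray-traced PSF (isoplanatic approximation)."""
    from scipy.ndimage import map_coordinates
    from scipy.signal import fftconvolve

    ny, nx = output_shape
    x = (np.arange(nx) - nx // 2) * output_pitch + output_center[0]
    y = (np.arange(ny) - ny // 2) * output_pitch + output_center[1]
    xx, yy = np.meshgrid(x, y)
    # object coordinates (mm) for each image sample (inverted image for m < 0)
    xo = xx / magnification
    yo = yy / magnification
    tx = target.x()
    ty = target.y()
    ci = (xo - tx[0]) / target.pitch
    ri = (yo - ty[0]) / target.pitch
    ideal = map_coordinates(target.transmission, [ri, ci], order=1,
                            mode="constant", cval=0.0)
    kern = psf / psf.sum()
    img = fftconvolve(ideal, kern, mode="same")
    return np.clip(img, 0.0, None)
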