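"""Model-eye optical bench: assembly, calibration, and misalignment poses.

The bench reproduces a wet-cell IOL test setup: a collimated 543.5-nm laser
passes an object mask and a 9.072-mm aperture stop, refracts at a
single-surface aspheric artificial cornea (43 D into aqueous, conic -0.26),
crosses a water cell bounded by plane BK7 windows, traverses the 20 D
SA-correcting IOL, and lands on a screen.  Three calibrations fix the
geometry that the optical prescription leaves open:

* ``calibrate_stop_to_pupil`` — the cornea-to-IOL distance at which the
  paraxial marginal ray of the stop spans the 5-mm design pupil on the IOL;
* ``calibrate_iol_asphere`` — the front-surface a4 that nulls the aligned
  bench's exit-pupil Z(4,0) (the SA-correcting property);
* ``find_focal_plane`` — the screen position maximizing the field-traced
  axial peak with the mask removed; fixed during misalignment sweeps.

All distances are bookkept both physically and as reduced lengths (t/n), so
the plane windows enter the wave-optics chain purely as reduced path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as _dc_field

import numpy as np
import yaml
from scipy.optimize import brentq, minimize_scalar

from . import field_core as fc
from .field_core import ComplexField, OPDMap
from .surfaces import (ConicAsphericSurface, LensElement, element_opd_map,
                       interface_eikonal_profile, interface_opd_map,
                       paraxial_power)
from .targets import generate_plane_wave

__all__ = ["BenchConfig", "ModelEyeBench", "build_bench",
           "calibrate_stop_to_pupil", "calibrate_iol_asphere",
           "find_focal_plane", "set_misalignment", "field_at_exit",
           "field_psf", "predicted_image_center", "cornea_wavefront_z40",
           "system_z40", "mask_conjugate", "ray_psf"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class BenchConfig:
    """All bench tunables; round-trips losslessly through YAML."""

    wavelength_nm: float = 543.5
    stop_diameter: float = 9.072          # mm
    pupil_diameter: float = 5.0           # mm, design pupil at the IOL
    cornea_power_d: float = 43.0
    cornea_conic: float = -0.26
    cornea_semi_aperture: float = 5.8     # mm
    n_air: float = 1.0
    n_aqueous: float = 1.336
    n_window: float = 1.5195              # BK7 at 543.5 nm
    iol_power_d: float = 20.0
    iol_index: float = 1.47
    iol_thickness: float = 0.9            # mm
    iol_optic_diameter: float = 7.0       # mm
    window_thickness: float = 1.0         # mm each
    window1_gap: float = 2.0              # mm water, cornea -> window 1
    window2_gap: float = 1.0              # mm water, IOL back -> window 2
    mask_to_stop: float = 240.0           # mm air
    stop_to_cornea: float = 10.0          # mm air
    grid_n: int = 2048
    grid_window: float = 13.6             # mm (1.5 x stop diameter)
    psf_pitch_um: float = 0.15
    psf_n: int = 1024
    refocus_per_pose: bool = False
    seed: int = 0

    def validate(self):
        bad = []
        for key in ("wavelength_nm", "stop_diameter", "pupil_diameter",
                    "cornea_power_d", "iol_power_d", "iol_index",
                    "iol_thickness", "window_thickness", "grid_window",
                    "psf_pitch_um"):
            if getattr(self, key) <= 0:
                bad.append(key)
        for key in ("n_air", "n_aqueous", "n_window"):
            if getattr(self, key) < 1:
                bad.append(key)
        if self.pupil_diameter >= self.stop_diameter:
            bad.append("pupil_diameter (must be smaller than the stop)")
        if self.grid_n < 64:
            bad.append("grid_n")
        if bad:
            raise ValueError("inconsistent config keys: " + ", ".join(bad))
        return self

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "BenchConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yml", ".yaml")):
                with open(text) as fh:
                    data = yaml.safe_load(fh)
            else:
                data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError("inconsistent config keys: " + ", ".join(sorted(unknown)))
        return cls(**data).validate()


# ---------------------------------------------------------------------------
# paraxial (reduced) 2x2 matrices
# ---------------------------------------------------------------------------

def mat_translate(t_reduced: float) -> np.ndarray:
    return np.array([[1.0, t_reduced], [0.0, 1.0]])

def mat_power(P_mm: float) -> np.ndarray:
    return np.array([[1.0, 0.0], [-P_mm, 1.0]])


# ---------------------------------------------------------------------------
# bench
# ---------------------------------------------------------------------------

@dataclass
class ModelEyeBench:
    config: BenchConfig
    cornea: ConicAsphericSurface = None
    iol: LensElement = None
    z_mask: float = 0.0
    z_stop: float = 0.0
    z_cornea: float = 0.0
    z_w1: float = 0.0            # window-1 front face
    z_iol: float = 0.0           # IOL front vertex (un-posed)
    z_w2: float = 0.0            # window-2 front face
    z_ref: float = 0.0           # exit reference plane (window-2 back face)
    screen_z: float | None = None

    # -- derived quantities ------------------------------------------------
    @property
    def iol_pose(self):
        return (self.iol.decenter_y, self.iol.tilt_y)

    @property
    def cornea_power_mm(self) -> float:
        return self.config.cornea_power_d * 1e-3

    @property
    def iol_power_mm(self) -> float:
        return self.config.iol_power_d * 1e-3

    def reduced_t1(self) -> float:
        """Reduced path, cornea vertex -> IOL front vertex."""
        c = self.config
        g2 = self.z_iol - (self.z_w1 + c.window_thickness)
        return (c.window1_gap / c.n_aqueous + c.window_thickness / c.n_window
                + g2 / c.n_aqueous)

    def reduced_t2(self) -> float:
        """Reduced path, IOL back vertex -> exit reference plane."""
        c = self.config
        return c.window2_gap / c.n_aqueous + c.window_thickness / c.n_window

    def iol_half_reduced(self) -> float:
        """Half the IOL's internal reduced path.  The projected thin screen
        sits at the reduced midplane, which for a symmetric biconvex lens
        coincides with both principal planes."""
        return 0.5 * self.config.iol_thickness / self.config.iol_index

    def reduced_air(self) -> float:
        return (self.z_cornea - self.z_mask) / self.config.n_air

    def exit_curvature(self) -> float:
        """Reduced carrier curvature of the axial beam at the reference plane
        (follows the field chain: cornea power, hop to the IOL midplane, IOL
        design power, hop to the reference plane)."""
        Pc, Pi = self.cornea_power_mm, self.iol_power_mm
        th = self.iol_half_reduced()
        C1 = Pc
        C2 = C1 / (1 - (self.reduced_t1() + th) * C1) + Pi
        return C2 / (1 - (th + self.reduced_t2()) * C2)

    def screen_zr(self, screen_z: float | None = None) -> float:
        """Reduced distance from the reference plane to the screen."""
        z = self.screen_z if screen_z is None else screen_z
        if z is None:
            raise RuntimeError("screen not set; run find_focal_plane first")
        return (z - self.z_ref) / self.config.n_aqueous

    def system_matrix(self, from_mask=False) -> np.ndarray:
        """Reduced ray-transfer matrix, stop (or mask) plane -> reference plane."""
        c = self.config
        th = self.iol_half_reduced()
        M = mat_translate(th + self.reduced_t2()) @ mat_power(self.iol_power_mm) \
            @ mat_translate(self.reduced_t1() + th) @ mat_power(self.cornea_power_mm) \
            @ mat_translate(c.stop_to_cornea / c.n_air)
        if from_mask:
            M = M @ mat_translate(c.mask_to_stop / c.n_air)
        return M

    # -- ray train for the comparator engine -------------------------------
    def ray_train(self, ideal: bool = False):
        c = self.config
        plane = lambda semi: ConicAsphericSurface(np.inf, semi_aperture=semi)
        wsemi = 12.0
        ops = []
        if ideal:
            ops.append(("ideal", self.cornea_power_mm, self.z_cornea,
                        c.n_air, c.n_aqueous))
            ops.append(("ideal", self.iol_power_mm,
                        self.z_iol + c.iol_thickness / 2, c.n_aqueous,
                        c.n_aqueous))
        else:
            ops.append(("interface", self.cornea, self.z_cornea,
                        c.n_air, c.n_aqueous))
            ops.append(("interface", plane(wsemi), self.z_w1,
                        c.n_aqueous, c.n_window))
            ops.append(("interface", plane(wsemi),
                        self.z_w1 + c.window_thickness, c.n_window, c.n_aqueous))
            ops.append(("lens", self.iol, self.z_iol, c.n_aqueous, c.n_aqueous))
            ops.append(("interface", plane(wsemi), self.z_w2,
                        c.n_aqueous, c.n_window))
            ops.append(("interface", plane(wsemi),
                        self.z_w2 + c.window_thickness, c.n_window, c.n_aqueous))
        ops.append(("plane", self.z_ref, c.n_aqueous))
        return ops

    def provenance(self) -> str:
        lines = ["# resolved bench parameters"]
        for k, v in dataclasses.asdict(self.config).items():
            lines.append(f"config.{k}: {v}")
        for k in ("z_mask", "z_stop", "z_cornea", "z_w1", "z_iol", "z_w2",
                  "z_ref", "screen_z"):
            lines.append(f"{k}: {getattr(self, k)}")
        lines.append(f"cornea.radius: {self.cornea.radius}")
        lines.append(f"iol.front.radius: {self.iol.front.radius}")
        lines.append(f"iol.back.radius: {self.iol.back.radius}")
        lines.append(f"iol.front.a4: {self.iol.front.a4}")
        lines.append(f"iol.front.a6: {self.iol.front.a6}")
        lines.append(f"iol.pose: {self.iol_pose}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# construction and calibrations
# ---------------------------------------------------------------------------

def _iol_radius_for_power(config: BenchConfig) -> float:
    """Equal-radii biconvex radius giving the design power in water."""
    def power_of(R):
        el = LensElement(
            ConicAsphericSurface(R, semi_aperture=config.iol_optic_diameter / 2),
            ConicAsphericSurface(-R, semi_aperture=config.iol_optic_diameter / 2),
            config.iol_thickness, config.iol_index)
        return paraxial_power(el, config.n_aqueous, config.n_aqueous)
    return brentq(lambda R: power_of(R) - config.iol_power_d, 2.0, 200.0,
                  xtol=1e-10)


def calibrate_stop_to_pupil(bench: ModelEyeBench,
                            target_pupil: float | None = None) -> float:
    """Solve the cornea->IOL spacing so the stop's paraxial marginal ray spans
    ``target_pupil`` at the IOL plane; returns the stop's axial position.

    The collimated marginal ray at the stop edge (height D_stop/2) refracts at
    the cornea and must arrive at the IOL plane at height target_pupil/2; the
    required reduced spacing is (1 - pupil/stop)/P_cornea.  Verified
    independently with a paraxial two-ray trace in the caller's tests.
    """
    c = bench.config
    target = c.pupil_diameter if target_pupil is None else target_pupil
    if not 0 < target < c.stop_diameter:
        raise ValueError("no physical solution: need 0 < pupil < stop diameter")
    T1 = (1.0 - target / c.stop_diameter) / bench.cornea_power_mm
    fixed = (c.window1_gap / c.n_aqueous
             + c.window_thickness / c.n_window)
    g2 = (T1 - fixed) * c.n_aqueous
    if g2 <= 0:
        raise ValueError("no solution: wet-cell window leaves no room before "
                         "the IOL at this pupil ratio")
    bench.z_w1 = bench.z_cornea + c.window1_gap
    bench.z_iol = bench.z_w1 + c.window_thickness + g2
    bench.z_w2 = bench.z_iol + c.iol_thickness + c.window2_gap
    bench.z_ref = bench.z_w2 + c.window_thickness
    return bench.z_stop


def marginal_ray_height_at_iol(bench: ModelEyeBench) -> float:
    """Independent paraxial trace of the stop's marginal ray to the IOL plane."""
    c = bench.config
    y, u = c.stop_diameter / 2.0, 0.0          # reduced angle
    # stop -> cornea (air)
    y += u * c.stop_to_cornea / c.n_air
    u -= bench.cornea_power_mm * y
    # cornea -> IOL front vertex, segment by segment
    for (t, n) in ((c.window1_gap, c.n_aqueous),
                   (c.window_thickness, c.n_window),
                   (bench.z_iol - bench.z_w1 - c.window_thickness, c.n_aqueous)):
        y += u * t / n
    return y


def build_bench(config: BenchConfig | None = None,
                calibrate_asphere: bool = True) -> ModelEyeBench:
    """Assemble the bench from a config and run the geometry calibrations."""
    config = (config or BenchConfig()).validate()
    c = config
    cornea_radius = (c.n_aqueous - c.n_air) / (c.cornea_power_d * 1e-3)
    cornea = ConicAsphericSurface(cornea_radius, c.cornea_conic,
                                  semi_aperture=c.cornea_semi_aperture)
    R = _iol_radius_for_power(c)
    semi = c.iol_optic_diameter / 2.0
    iol = LensElement(ConicAsphericSurface(R, semi_aperture=semi),
                      ConicAsphericSurface(-R, semi_aperture=semi),
                      c.iol_thickness, c.iol_index)
    bench = ModelEyeBench(config=config, cornea=cornea, iol=iol)
    bench.z_mask = 0.0
    bench.z_stop = c.mask_to_stop
    bench.z_cornea = bench.z_stop + c.stop_to_cornea
    calibrate_stop_to_pupil(bench)
    iol.axial_position = bench.z_iol
    if calibrate_asphere:
        calibrate_iol_asphere(bench)
    return bench


def _paraxial_focus_z(bench: ModelEyeBench) -> float:
    return bench.z_ref + bench.config.n_aqueous / bench.exit_curvature()


def system_z40(bench: ModelEyeBench, ideal_iol: bool = False,
               zone_fraction: float = 1.0, n_rings: int = 32) -> float:
    """Exit-pupil Z(4,0) (um) of the bench by exact ray trace.

    ``zone_fraction`` restricts the Zernike fit zone to that fraction of the
    traced pupil footprint (e.g. the 6-mm corneal zone is 6/stop_diameter).
    ``ideal_iol`` swaps the real IOL for an aberration-free phase lens of the
    same paraxial power (the SA-compensation probe).
    """
    from .metrics import zernike_fit, zernike_coefficient
    from .raytrace import exit_pupil_opd, trace_bundle

    train = bench.ray_train()
    if ideal_iol:
        # An aberration-free phase lens of the same power adds zero wavefront
        # aberration and a pure defocus (absorbed by the Zernike fit), so the
        # probe traces the train without the IOL and references its own
        # paraxial focus.
        train = [op for op in train if op[0] != "lens"]
        Pc = bench.cornea_power_mm
        t_total = (bench.reduced_t1() + bench.config.iol_thickness
                   / bench.config.n_aqueous + bench.reduced_t2())
        C_exit = Pc / (1.0 - t_total * Pc)
        focus = (0.0, 0.0, bench.z_ref + bench.config.n_aqueous / C_exit)
    else:
        focus = (0.0, 0.0, _paraxial_focus_z(bench))
    holder = _TrainBench(bench, train)
    bundle = trace_bundle(holder, n_rings=n_rings)
    opd = exit_pupil_opd(bundle, focus, bench.config.n_aqueous)
    if zone_fraction >= 1.0:
        zone = opd.aperture_diameter
    else:
        # exact ray mapping of the zone edge: exit radius of the rays
        # launched at zone_fraction of the stop radius
        alive = bundle.alive
        r_launch = np.hypot(*bundle.pupil_coords[alive].T)
        r_exit = np.hypot(bundle.positions[alive, 0],
                          bundle.positions[alive, 1])
        order = np.argsort(r_launch)
        zone = 2.0 * np.interp(zone_fraction, r_launch[order], r_exit[order])
    table = zernike_fit(opd, aperture_diameter=zone)
    return zernike_coefficient(table, 4, 0)


class _TrainBench:
    """Adapter exposing a fixed ray train with the bench's launch geometry."""

    def __init__(self, bench, train):
        self.config = bench.config
        self.z_stop = bench.z_stop
        self._train = train

    def ray_train(self):
        return self._train


def _system_z_mode(bench, n, m) -> float:
    from .metrics import zernike_fit, zernike_coefficient
    from .raytrace import exit_pupil_opd, trace_bundle
    bundle = trace_bundle(_TrainBench(bench, bench.ray_train()), n_rings=32)
    focus = (0.0, 0.0, _paraxial_focus_z(bench))
    opd = exit_pupil_opd(bundle, focus, bench.config.n_aqueous)
    return zernike_coefficient(zernike_fit(opd), n, m)


def calibrate_iol_asphere(bench: ModelEyeBench, tol_um: float = 0.005,
                          with_a6: bool = True) -> float:
    """Front-surface a4 (and a6) nulling the aligned bench's exit-pupil SA.

    a4 is root-found to null Z(4,0); with ``with_a6`` an outer root-find on
    a6 also nulls the secondary term Z(6,0).  Both are deterministic scalar
    root-finds; paraxial power is unaffected (r^4/r^6 carry no curvature).
    Raises if the Z(4,0) residual exceeds ``tol_um``.
    """
    if bench.iol_pose != (0.0, 0.0):
        raise RuntimeError("calibrate on the aligned bench")

    def solve_a4():
        def z40_of(a4):
            bench.iol.front.a4 = a4
            return system_z40(bench)
        a4 = brentq(z40_of, -1.5e-2, 1.5e-2, xtol=1e-9)
        bench.iol.front.a4 = a4
        return a4

    if with_a6:
        def z60_of(a6):
            bench.iol.front.a6 = a6
            solve_a4()
            return _system_z_mode(bench, 6, 0)
        a6 = brentq(z60_of, -5e-4, 5e-4, xtol=1e-10, rtol=1e-6)
        bench.iol.front.a6 = a6
    a4 = solve_a4()
    resid = abs(system_z40(bench))
    if resid > tol_um:
        raise RuntimeError(f"asphere calibration residual |Z40| = "
                           f"{resid:.4f} um exceeds {tol_um} um")
    return a4


def cornea_wavefront_z40(config: BenchConfig | None = None,
                         zone_diameter: float = 6.0,
                         n_rings: int = 32) -> float:
    """Z(4,0) (um) of the model cornea alone over ``zone_diameter``.

    Collimated bundle through the single aspheric surface; OPD against the
    reference sphere centered at the paraxial focus; OSA Zernike fit.
    """
    from .metrics import zernike_fit, zernike_coefficient
    from .raytrace import RayBundle, _trace_interface, exit_pupil_opd, \
        hexapolar_coordinates

    config = (config or BenchConfig()).validate()
    radius = (config.n_aqueous - config.n_air) / (config.cornea_power_d * 1e-3)
    cornea = ConicAsphericSurface(radius, config.cornea_conic,
                                  semi_aperture=zone_diameter / 2 + 0.2)
    coords = hexapolar_coordinates(n_rings)
    N = len(coords)
    pos = np.zeros((N, 3))
    pos[:, :2] = coords * (zone_diameter / 2.0)
    pos[:, 2] = -5.0
    bundle = RayBundle(pos, np.tile([0.0, 0.0, 1.0], (N, 1)),
                       np.zeros(N), np.ones(N, bool), coords)
    bundle.opl += 5.0 * config.n_air        # reach z=0 reference
    _trace_interface(bundle, cornea, 0.0, config.n_air, config.n_aqueous)
    focus = (0.0, 0.0, config.n_aqueous / (config.cornea_power_d * 1e-3))
    opd = exit_pupil_opd(bundle, focus, config.n_aqueous)
    # fit over the physical zone, not the (slightly smaller) hexapolar hull
    table = zernike_fit(opd, aperture_diameter=zone_diameter)
    return zernike_coefficient(table, 4, 0)


# ---------------------------------------------------------------------------
# field-engine chain
# ---------------------------------------------------------------------------

def _apply_screen(field: ComplexField, opd_um: np.ndarray,
                  power_mm: float) -> ComplexField:
    """Thin refracting screen: full OPD applied, paraxial quadratic moved into
    the carrier in a single well-sampled multiplication."""
    lam_um = field.wavelength * 1e-3
    lam_mm = field.wavelength_mm
    xx, yy = field.grid()
    r2 = xx ** 2 + yy ** 2
    phase = 2 * np.pi * np.where(np.isfinite(opd_um), opd_um, 0.0) / lam_um \
        + np.pi * power_mm * r2 / lam_mm
    amp = field.amplitude * np.where(np.isfinite(opd_um),
                                     np.exp(1j * phase), 0.0)
    return dataclasses.replace(field, amplitude=amp,
                               carrier_curvature=field.carrier_curvature
                               + power_mm)


def field_at_exit(bench: ModelEyeBench, ideal: bool = False,
                  mask=None, grid_n: int | None = None) -> ComplexField:
    """Propagate the coherent input to the exit reference plane.

    Returns a carrier-referenced field (residual V, parabolic carrier) just
    after the wet cell.  ``ideal=True`` replaces cornea and IOL by
    aberration-free phase elements of the same paraxial powers (the Strehl
    reference bench); ``mask`` switches from plane-wave (PSF) input to the
    imaging input.
    """
    c = bench.config
    n = grid_n or c.grid_n
    pitch = c.grid_window / n
    f = generate_plane_wave(n, pitch, c.wavelength_nm, medium_index=c.n_air)
    if mask is not None:
        from scipy.ndimage import map_coordinates
        tx, ty = mask.x(), mask.y()
        ci = (f.x() - tx[0]) / mask.pitch
        ri = (f.y() - ty[0]) / mask.pitch
        cc, rr = np.meshgrid(ci, ri)
        t = map_coordinates(mask.transmission, [rr, cc], order=1,
                            mode="constant", cval=0.0)
        f = dataclasses.replace(f, amplitude=f.amplitude * t)
        f = fc.propagate_angular_spectrum(f, c.mask_to_stop)
    f = fc.apply_aperture(f, c.stop_diameter)
    f = fc.propagate_angular_spectrum(f, c.stop_to_cornea)
    # cornea
    f = fc.apply_aperture(f, 2 * c.cornea_semi_aperture)
    if ideal:
        f = fc.absorb_parabolic_phase(f, bench.cornea_power_mm)
    else:
        xx, yy = f.grid()
        rr = np.hypot(xx, yy)
        r0, w0 = interface_eikonal_profile(bench.cornea, c.n_air, c.n_aqueous,
                                           c.cornea_semi_aperture)
        opd = np.where(rr <= r0.max(), np.interp(rr, r0, w0), np.nan)
        f = _apply_screen(f, opd, bench.cornea_power_mm)
    # hop to the IOL reduced midplane (windows are pure bookkeeping)
    T1 = bench.reduced_t1() + bench.iol_half_reduced()
    M1 = 1.0 - T1 * f.carrier_curvature
    f = fc.propagate_scaled(f, T1, medium_index=1.0,
                            output_pitch=f.pitch_x * M1, keep_carrier=True)
    # IOL
    if ideal:
        f = fc.apply_aperture(f, c.iol_optic_diameter)
        f = fc.absorb_parabolic_phase(f, bench.iol_power_mm)
    else:
        xx, yy = f.grid()
        opd = element_opd_map(bench.iol, xx, yy, c.n_aqueous, c.n_aqueous,
                              pitch=f.pitch_x,
                              incident_cone=f.carrier_curvature)
        rel = opd.opd - np.nanmax(opd.opd)
        f = _apply_screen(f, rel, bench.iol_power_mm)
    # hop to the exit reference plane
    T2 = bench.iol_half_reduced() + bench.reduced_t2()
    M2 = 1.0 - T2 * f.carrier_curvature
    f = fc.propagate_scaled(f, T2, medium_index=1.0,
                            output_pitch=f.pitch_x * M2, keep_carrier=True)
    return f


def _fresnel_fan_exit_opd(bench: ModelEyeBench, heights: np.ndarray):
    """Meridional fan through the thin screens with *paraxial* transport.

    Returns (x_exit, w_um): exit radius and parabola-referenced OPD of the
    field chain's own (Fresnel-kernel) world — the phase the carrier-referenced
    residual V accumulates, evaluated by stationary-phase ray bookkeeping.
    """
    c = bench.config
    eps = 1e-6
    r0, w0 = interface_eikonal_profile(bench.cornea, c.n_air, c.n_aqueous,
                                       c.cornea_semi_aperture)
    Pc = bench.cornea_power_mm
    T1c = bench.reduced_t1() + bench.iol_half_reduced()
    C_mid = Pc / (1.0 - T1c * Pc)

    def Wc(r):
        return np.interp(r, r0, w0) * 1e-3    # mm

    def Wi(r):
        rr = np.atleast_2d(r)
        m = element_opd_map(bench.iol, rr, np.zeros_like(rr),
                            c.n_aqueous, c.n_aqueous, pitch=1.0,
                            incident_cone=C_mid)
        return m.opd[0] * 1e-3

    x = heights.astype(float).copy()
    u = np.zeros_like(x)
    opl = Wc(x)
    u = u + (Wc(x + eps) - Wc(x - eps)) / (2 * eps)
    T1 = bench.reduced_t1() + bench.iol_half_reduced()
    opl = opl + T1 * u ** 2 / 2.0
    x = x + T1 * u
    opl = opl + Wi(x)
    u = u + (Wi(x + eps) - Wi(x - eps)) / (2 * eps)
    T2 = bench.iol_half_reduced() + bench.reduced_t2()
    opl = opl + T2 * u ** 2 / 2.0
    x = x + T2 * u
    w = opl + bench.exit_curvature() * x ** 2 / 2.0
    w = w - w[0]
    return x, w * 1e3          # um


def _exact_fan_exit_opd(bench: ModelEyeBench, heights: np.ndarray):
    """Meridional fan with exact Snell refraction and slant-path OPLs;
    sphere-referenced exit OPD (reference sphere about the paraxial focus).

    Sign convention matches the field phase (ray OPL excess, not its
    negative), so the two fans are directly comparable."""
    from .raytrace import RayBundle, _advance_to_plane, _trace_interface, \
        _trace_lens
    N = len(heights)
    pos = np.zeros((N, 3))
    pos[:, 0] = heights
    pos[:, 2] = bench.z_stop
    coords = np.zeros((N, 2))
    coords[:, 0] = heights / (bench.config.stop_diameter / 2.0)
    bundle = RayBundle(pos, np.tile([0.0, 0.0, 1.0], (N, 1)),
                       np.zeros(N), np.ones(N, bool), coords)
    for op in bench.ray_train():
        if op[0] == "interface":
            _trace_interface(bundle, op[1], op[2], op[3], op[4])
        elif op[0] == "lens":
            _trace_lens(bundle, op[1], op[3], op[4])
        elif op[0] == "plane":
            _advance_to_plane(bundle, op[1], op[2])
    n_aq = bench.config.n_aqueous
    cz = _paraxial_focus_z(bench)
    p = bundle.positions
    d = bundle.directions
    Rref = cz - bench.z_ref
    dp = p - np.array([0.0, 0.0, cz])
    b = np.sum(dp * d, axis=1)
    disc = b * b - (np.sum(dp * dp, axis=1) - Rref * Rref)
    t = -b - np.sqrt(np.maximum(disc, 0.0))
    total = bundle.opl + n_aq * t
    w = total - total[0]
    r_exit = np.hypot(p[:, 0], p[:, 1])
    return r_exit, w * 1e3      # um


def transport_correction(bench: ModelEyeBench, n_samples: int = 160):
    """Nonparaxial transport-consistency map of the aligned bench.

    The field chain transports the carrier-referenced residual with paraxial
    (Fresnel/Talanov) kernels, which at this bench's NA (~0.19) under-count
    the slant-path optical length of the converging cone by an r^4-and-higher
    phase.  The map is the difference between the exact-world (vector Snell,
    slant paths, sphere reference) and Fresnel-world exit OPDs of the same
    aligned train, as a radial profile in exit-pupil coordinates.  It is a
    deterministic property of the aligned geometry, computed once per bench
    and held fixed for all misalignment poses.

    Returns a callable corr_um(r_mm).
    """
    aligned = bench if bench.iol_pose == (0.0, 0.0) \
        else set_misalignment(bench, 0.0, 0.0)
    hmax = 0.999 * bench.config.stop_diameter / 2.0
    heights = np.linspace(1e-6, hmax, n_samples)
    x_fr, w_fr = _fresnel_fan_exit_opd(aligned, heights)
    r_ex, w_ex = _exact_fan_exit_opd(aligned, heights)
    rg = np.linspace(0.0, max(x_fr.max(), r_ex.max()), n_samples)
    corr = np.interp(rg, r_ex, w_ex) - np.interp(rg, x_fr, w_fr)

    def corr_um(r):
        return np.interp(np.abs(r), rg, corr)
    return corr_um


def _corrected_pupil(bench: ModelEyeBench, field: ComplexField) -> np.ndarray:
    """Apply the cached transport-consistency phase to the exit residual."""
    if getattr(bench, "_transport_corr", None) is None:
        bench._transport_corr = transport_correction(bench)
    corr = bench._transport_corr
    lam_um = field.wavelength * 1e-3
    xx, yy = field.grid()
    r = np.hypot(xx, yy)
    return field.amplitude * np.exp(2j * np.pi * corr(r) / lam_um)


def field_psf(bench: ModelEyeBench, exit_field: ComplexField | None = None,
              screen_z: float | None = None, ideal: bool = False,
              output_center: tuple[float, float] | str = "auto",
              grid_n: int | None = None,
              psf_n: int | None = None) -> tuple[np.ndarray, dict]:
    """Field-traced screen intensity for a plane-wave (mask-removed) input.

    Returns (intensity raster, info dict with pitch_um/center/zr).  The
    intensities of different poses and of the ideal reference are directly
    comparable (same input power and transform normalization).
    """
    c = bench.config
    if exit_field is None:
        exit_field = field_at_exit(bench, ideal=ideal, grid_n=grid_n)
    zr_screen = bench.screen_zr(screen_z)
    C = exit_field.carrier_curvature
    if ideal:
        pupil = exit_field.amplitude
    else:
        pupil = _corrected_pupil(bench, exit_field)
    if output_center == "auto":
        output_center = (0.0, 0.0) if ideal else predicted_image_center(bench)
    npsf = psf_n or c.psf_n
    out_pitch = c.psf_pitch_um * 1e-3
    fld = fc.pupil_to_focus(pupil, exit_field.pitch_x, c.wavelength_nm,
                            zr=1.0 / C, output_pitch=out_pitch,
                            output_shape=(npsf, npsf),
                            output_center=output_center,
                            defocus=zr_screen - 1.0 / C)
    info = dict(pitch_um=c.psf_pitch_um, center=output_center,
                zr=zr_screen, carrier=C)
    return np.abs(fld) ** 2, info


def reference_psf(bench: ModelEyeBench, grid_n: int | None = None,
                  psf_n: int | None = None) -> tuple[np.ndarray, dict]:
    """PSF of the ideal-phase-element reference bench at its own best focus.

    Same stop, apertures, paraxial powers and input power as the real bench,
    but aberration-free elements: the Strehl denominator."""
    c = bench.config
    ref_exit = field_at_exit(bench, ideal=True, grid_n=grid_n)
    C = ref_exit.carrier_curvature

    def neg_peak(zr):
        fld = fc.pupil_to_focus(ref_exit.amplitude, ref_exit.pitch_x,
                                c.wavelength_nm, 1.0 / C, 0.3e-3, (32, 32),
                                defocus=zr - 1.0 / C)
        return -float(np.abs(fld).max() ** 2)

    zr0 = 1.0 / C
    res = minimize_scalar(neg_peak, bounds=(zr0 - 1.0, zr0 + 1.0),
                          method="bounded", options={"xatol": 5e-4})
    npsf = psf_n or c.psf_n
    fld = fc.pupil_to_focus(ref_exit.amplitude, ref_exit.pitch_x,
                            c.wavelength_nm, 1.0 / C,
                            c.psf_pitch_um * 1e-3, (npsf, npsf),
                            defocus=res.x - 1.0 / C)
    info = dict(pitch_um=c.psf_pitch_um, center=(0.0, 0.0), zr=res.x, carrier=C)
    return np.abs(fld) ** 2, info


def find_focal_plane(bench: ModelEyeBench, grid_n: int | None = None,
                     set_screen: bool = True,
                     require_aligned: bool = True) -> float:
    """Screen position maximizing the bench's field-traced peak.

    Plane-wave input (mask removed), bracketed axial scan with golden-section
    refinement to ~1 um.  The result is fixed for all poses of a sweep
    (``require_aligned`` guards against accidentally focusing a posed bench;
    per-pose refocusing passes False).
    """
    if require_aligned and bench.iol_pose != (0.0, 0.0):
        raise RuntimeError("focus on the aligned bench, then apply poses")
    c = bench.config
    exit_field = field_at_exit(bench, grid_n=grid_n)
    C = exit_field.carrier_curvature
    pupil = _corrected_pupil(bench, exit_field)

    def neg_peak(zr):
        fld = fc.pupil_to_focus(pupil, exit_field.pitch_x, c.wavelength_nm,
                                zr=1.0 / C, output_pitch=0.3e-3,
                                output_shape=(32, 32),
                                defocus=zr - 1.0 / C)
        return -float(np.abs(fld).max() ** 2)

    zr0 = 1.0 / C
    res = minimize_scalar(neg_peak, bracket=None,
                          bounds=(zr0 - 1.0, zr0 + 1.0), method="bounded",
                          options={"xatol": 5e-4})
    if not res.success:
        raise RuntimeError("no interior focal maximum found in the bracket")
    screen = bench.z_ref + res.x * c.n_aqueous
    if set_screen:
        bench.screen_z = screen
    return screen


def set_misalignment(bench: ModelEyeBench, decenter_y_um: float,
                     tilt_y_deg: float) -> ModelEyeBench:
    """Posed copy of the bench: IOL shifted along y (um) / rotated about y
    (degrees); every other element and the screen stay fixed."""
    iol = dataclasses.replace(
        bench.iol,
        front=dataclasses.replace(bench.iol.front),
        back=dataclasses.replace(bench.iol.back),
        decenter_y=decenter_y_um, tilt_y=tilt_y_deg)
    return dataclasses.replace(bench, iol=iol)


def predicted_image_center(bench: ModelEyeBench) -> tuple[float, float]:
    """Chief-ray landing point on the screen (exact single-ray trace)."""
    from .raytrace import RayBundle, trace_bundle
    import copy
    from .raytrace import _advance_to_plane, _launch
    coords = np.zeros((1, 2))
    pos = np.array([[0.0, 0.0, bench.z_stop]])
    dirs = np.array([[0.0, 0.0, 1.0]])
    bundle = RayBundle(pos, dirs, np.zeros(1), np.ones(1, bool), coords)
    from .raytrace import _trace_interface, _trace_lens, _trace_ideal_lens
    for op in bench.ray_train():
        if op[0] == "interface":
            _trace_interface(bundle, op[1], op[2], op[3], op[4])
        elif op[0] == "lens":
            _trace_lens(bundle, op[1], op[3], op[4])
        elif op[0] == "ideal":
            _trace_ideal_lens(bundle, op[1], op[2], op[3], op[4])
        elif op[0] == "plane":
            _advance_to_plane(bundle, op[1], op[2])
    z = bench.screen_z if bench.screen_z is not None else _paraxial_focus_z(bench)
    _advance_to_plane(bundle, z, bench.config.n_aqueous)
    return (float(bundle.positions[0, 0]), float(bundle.positions[0, 1]))


def ray_psf(bench: ModelEyeBench, n_rings: int = 64,
            output_center: tuple[float, float] | str = "auto",
            psf_n: int | None = None) -> tuple[np.ndarray, dict]:
    """Ray-engine PSF on the same screen grid as the field engine.

    Exit-pupil OPD against the reference sphere centered on the aligned
    image point on the fixed screen, then the shared pupil-function
    chirp-z transform.  Normalized so the aberration-free same-pupil PSF
    peaks at 1 (ray-engine Strehl reference).
    """
    from .raytrace import exit_pupil_opd, psf_from_pupil, trace_bundle
    c = bench.config
    bundle = trace_bundle(bench, n_rings=n_rings)
    z = bench.screen_z if bench.screen_z is not None else _paraxial_focus_z(bench)
    opd = exit_pupil_opd(bundle, (0.0, 0.0, z), c.n_aqueous,
                         grid_n=min(c.grid_n, 256))
    if output_center == "auto":
        output_center = predicted_image_center(bench)
    zr = (z - bench.z_ref) / c.n_aqueous
    npsf = psf_n or c.psf_n
    psf = psf_from_pupil(opd, c.wavelength_nm, zr, c.psf_pitch_um * 1e-3,
                         (npsf, npsf), output_center)
    info = dict(pitch_um=c.psf_pitch_um, center=output_center, zr=zr, opd=opd)
    return psf, info


def mask_conjugate(bench: ModelEyeBench) -> tuple[float, float]:
    """(screen_z, magnification) of the object-mask conjugate plane."""
    M = bench.system_matrix(from_mask=True)
    A, B, Cm, D = M[0, 0], M[0, 1], M[1, 0], M[1, 1]
    zr = -B / D
    mag = A + zr * Cm
    return bench.z_ref + zr * bench.config.n_aqueous, mag
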