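"""Scalar harmonic-field representation and diffraction propagation.

The field engine propagates a sampled, fully coherent, monochromatic scalar
field between the planes of the optical bench.  Free-space hops use the
angular-spectrum (spectrum-of-plane-waves) method with the exact non-paraxial
transfer function and a Matsushima-style band limit that suppresses
wrap-around aliasing on long hops.

Strongly converging beams cannot be sampled directly on a bench-sized grid:
behind the model cornea the local fringe frequency of the converging phase
exceeds the grid Nyquist by a factor of ~5.  Such beams are therefore stored
as a slowly varying residual ``V`` times an analytic parabolic *carrier*,

    U(x, y) = V(x, y) * exp(-i * pi * C * r^2 / lambda0),

where ``C`` (1/mm) is the reduced carrier curvature (reduced = physical
distance divided by the medium index, which makes plane glass plates in the
train pure bookkeeping).  Propagation of a carrier-referenced field uses the
Talanov similarity transform: the carrier transports exactly as a converging
spherical wave (magnification ``M = 1 - z*C``), while the residual is
propagated over the reduced effective distance with the exact transfer
function.  Focal-region output planes are evaluated with a chirp-z (Bluestein)
Fresnel integral at an arbitrary output pitch and window center.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field, replace

import numpy as np
from scipy.signal import czt as _czt

__all__ = [
    "ComplexField",
    "OPDMap",
    "propagate_angular_spectrum",
    "propagate_scaled",
    "apply_aperture",
    "apply_phase_mask",
    "absorb_parabolic_phase",
    "pupil_to_focus",
]


@dataclass
class ComplexField:
    """A sampled 2-D complex scalar amplitude on a uniform grid.

    Parameters
    ----------
    amplitude : (ny, nx) complex ndarray
        Stored samples.  If ``carrier_curvature`` is nonzero these are the
        residual ``V``; the physical field is ``V * exp(-i*pi*C*r^2/lambda0)``.
    pitch_x, pitch_y : float
        Sample spacing in mm.
    wavelength : float
        Vacuum wavelength in nm.
    medium_index : float
        Refractive index of the surrounding medium.
    z : float
        Axial position of the plane in mm (bench frame).
    carrier_curvature : float
        Reduced curvature ``C`` (1/mm) of the analytic parabolic carrier;
        0 means the samples are the literal field.
    center_x, center_y : float
        Transverse position (mm) of the grid center sample, for windows that
        track an off-axis image point.
    """

    amplitude: np.ndarray
    pitch_x: float
    pitch_y: float
    wavelength: float
    medium_index: float = 1.0
    z: float = 0.0
    carrier_curvature: float = 0.0
    center_x: float = 0.0
    center_y: float = 0.0

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=np.complex128)
        if self.amplitude.ndim != 2 or min(self.amplitude.shape) < 2:
            raise ValueError("amplitude must be a 2-D grid with >= 2 samples per axis")
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ValueError("pitches must be positive")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude contains non-finite values")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self):
        return self.amplitude.shape

    @property
    def wavelength_mm(self) -> float:
        return self.wavelength * 1e-6

    def x(self) -> np.ndarray:
        nx = self.shape[1]
        return (np.arange(nx) - nx // 2) * self.pitch_x + self.center_x

    def y(self) -> np.ndarray:
        ny = self.shape[0]
        return (np.arange(ny) - ny // 2) * self.pitch_y + self.center_y

    def grid(self):
        return np.meshgrid(self.x(), self.y(), sparse=True)

    def power(self) -> float:
        """Total power: sum |V|^2 * pitch_x * pitch_y (carrier is unimodular)."""
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.pitch_x * self.pitch_y)

    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    def copy(self) -> "ComplexField":
        return replace(self, amplitude=self.amplitude.copy())


@dataclass
class OPDMap:
    """Optical path difference map over an aperture.

    ``opd`` is in micrometres on a grid with spacing ``pitch`` (mm);
    ``aperture_diameter`` (mm) is the reference zone.  Samples outside the
    traced/defined footprint are NaN.
    """

    opd: np.ndarray
    pitch: float
    aperture_diameter: float
    center_x: float = 0.0
    center_y: float = 0.0

    def __post_init__(self):
        self.opd = np.asarray(self.opd, dtype=float)
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        inside = self.mask()
        if inside.any() and not np.all(np.isfinite(self.opd[inside])):
            raise ValueError("non-finite OPD inside the aperture")

    def x(self):
        n = self.opd.shape[1]
        return (np.arange(n) - n // 2) * self.pitch

    def y(self):
        n = self.opd.shape[0]
        return (np.arange(n) - n // 2) * self.pitch

    def mask(self) -> np.ndarray:
        """Samples inside the declared zone (centered at center_x/center_y)."""
        xx, yy = np.meshgrid(self.x() - self.center_x, self.y() - self.center_y,
                             sparse=True)
        return (xx ** 2 + yy ** 2) <= (self.aperture_diameter / 2) ** 2


# ---------------------------------------------------------------------------
# angular spectrum propagation
# ---------------------------------------------------------------------------

def _asm_transfer(shape, pitch_x, pitch_y, lam, dist):
    """Exact non-paraxial transfer function with Matsushima band limit.

    ``lam`` is the wavelength in the propagation medium (mm), ``dist`` in mm.
    Returns H sampled on the fftfreq grid.
    """
    ny, nx = shape
    fx = np.fft.fftfreq(nx, d=pitch_x)
    fy = np.fft.fftfreq(ny, d=pitch_y)
    fx2 = fx[np.newaxis, :] ** 2
    fy2 = fy[:, np.newaxis] ** 2
    kap2 = 1.0 / lam ** 2
    arg = kap2 - fx2 - fy2
    prop = arg > 0
    H = np.zeros(shape, dtype=np.complex128)
    H[...] = 0.0
    sq = np.sqrt(np.where(prop, arg, 0.0))
    H = np.where(prop, np.exp(2j * np.pi * dist * sq), 0.0)
    # Matsushima-Shimobaba band limit: suppress frequencies whose plane-wave
    # direction would wrap around the periodic window over this distance.
    dfx = 1.0 / (nx * pitch_x)
    dfy = 1.0 / (ny * pitch_y)
    ad = abs(dist)
    if ad > 0:
        flx = 1.0 / (lam * np.sqrt((2.0 * dfx * ad) ** 2 + 1.0))
        fly = 1.0 / (lam * np.sqrt((2.0 * dfy * ad) ** 2 + 1.0))
        if flx < 4 * dfx or fly < 4 * dfy:
            need = int(np.ceil(4 * 2 * ad * lam / (pitch_x ** 2)))
            raise ValueError(
                "grid too small for band-limited propagation over "
                f"{dist} mm: need roughly >= {need} samples per axis at this pitch"
            )
        H = np.where((np.abs(fx)[np.newaxis, :] < flx)
                     & (np.abs(fy)[:, np.newaxis] < fly), H, 0.0)
    return H


def propagate_angular_spectrum(field: ComplexField, distance: float,
                               medium_index: float | None = None) -> ComplexField:
    """Propagate the *stored samples* by ``distance`` (mm) with the exact ASM.

    The stored samples are treated as the literal field, so the carrier
    curvature must be zero (carrier-referenced fields go through
    :func:`propagate_scaled`).  Evanescent components decay (are dropped) and
    the Matsushima band limit suppresses aliased frequencies; total power
    never increases.
    """
    if not np.isfinite(distance):
        raise ValueError("distance must be finite")
    if field.carrier_curvature != 0.0:
        raise ValueError("field has a parabolic carrier; use propagate_scaled")
    n = field.medium_index if medium_index is None else medium_index
    if n < 1:
        raise ValueError("medium_index must be >= 1")
    if distance == 0:
        out = field.copy()
        out.medium_index = n
        return out
    lam = field.wavelength_mm / n
    H = _asm_transfer(field.shape, field.pitch_x, field.pitch_y, lam, distance)
    spec = np.fft.fft2(field.amplitude)
    amp = np.fft.ifft2(spec * H)
    return replace(field, amplitude=amp, z=field.z + distance, medium_index=n)


# ---------------------------------------------------------------------------
# chirp-z scaled Fourier kernel
# ---------------------------------------------------------------------------

def _czt_axis(arr, axis, n_in, pitch_in, n_out, pitch_out, scale, center_out, center_in):
    """Evaluate S[m] = sum_k arr[k] exp(-2i*pi * x_k * u_m / scale) along ``axis``.

    x_k = (k - k0)*pitch_in + center_in, u_m = (m - m0)*pitch_out + center_out,
    with k0 = n_in//2, m0 = n_out//2.  Uses Bluestein's algorithm.
    """
    k0 = n_in // 2
    m0 = n_out // 2
    alpha = pitch_in * pitch_out / scale          # cycles per (k,m) step product
    w = np.exp(-2j * np.pi * alpha)
    # ramp from the output-center offset
    beta = pitch_in * center_out / scale
    a = np.exp(2j * np.pi * (beta - alpha * m0))  # czt evaluates a^{-k} w^{mk}
    x = np.moveaxis(arr, axis, -1)
    X = _czt(x, m=n_out, w=w, a=a)
    m = np.arange(n_out)
    # undo the k0 shift
    post = w ** (-k0 * (m - m0)) * np.exp(2j * np.pi * k0 * beta)
    # input-center offset against output coordinate
    post = post * np.exp(-2j * np.pi * center_in * ((m - m0) * pitch_out + center_out)
                         / scale)
    X = X * post
    return np.moveaxis(X, -1, axis)


def _scaled_ft(arr, pitch_in, pitch_out, shape_out, scale,
               center_in=(0.0, 0.0), center_out=(0.0, 0.0)):
    """2-D scaled Fourier integral sum f(x1) exp(-2i pi x1.x2/scale) d^2x1.

    Includes the dx1 dy1 area element.  ``scale`` = lambda * z (mm^2).
    """
    ny, nx = arr.shape
    oy, ox = shape_out
    out = _czt_axis(arr, 1, nx, pitch_in[0], ox, pitch_out[0], scale,
                    center_out[0], center_in[0])
    out = _czt_axis(out, 0, ny, pitch_in[1], oy, pitch_out[1], scale,
                    center_out[1], center_in[1])
    return out * pitch_in[0] * pitch_in[1]


# ---------------------------------------------------------------------------
# scaled propagation
# ---------------------------------------------------------------------------

def propagate_scaled(field: ComplexField, distance: float,
                     medium_index: float | None = None,
                     output_pitch: float | None = None,
                     output_shape: tuple[int, int] | None = None,
                     output_center: tuple[float, float] = (0.0, 0.0),
                     keep_carrier: bool = False) -> ComplexField:
    """Propagate to a plane sampled at ``output_pitch`` (mm).

    Two regimes are selected automatically:

    * If the single-step Fresnel chirp is resolvable on the input grid (the
      output plane is near the carrier focus), the field is evaluated by one
      chirp-z integral on the requested output grid (``output_shape``,
      ``output_center``).
    * Otherwise a Talanov similarity hop is used: the requested pitch defines
      the magnification, the residual is propagated with the exact-H ASM over
      the reduced effective distance, and the result keeps a parabolic
      carrier (materialized unless ``keep_carrier``).

    ``distance`` is the physical distance; propagation is computed in reduced
    distance ``distance / medium_index`` so plane windows elsewhere in the
    train may be folded in by the caller as reduced lengths.
    """
    if distance <= 0:
        raise ValueError("propagate_scaled requires distance > 0")
    n = field.medium_index if medium_index is None else medium_index
    lam = field.wavelength_mm
    zr = distance / n
    if output_pitch is None:
        output_pitch = field.pitch_x
    if output_pitch <= 0:
        raise ValueError("output_pitch must be positive")
    if output_shape is None:
        output_shape = field.shape
    C = field.carrier_curvature

    # single-step chirp coefficient: a = 1/zr - C
    a_chirp = 1.0 / zr - C
    xmax = max(abs(field.x()).max(), abs(field.y()).max())
    nyq_in = 0.5 / max(field.pitch_x, field.pitch_y)
    chirp_fmax = abs(a_chirp) * xmax / lam
    if chirp_fmax < 0.5 * nyq_in or _chirped_product_resolved(field, a_chirp):
        return _single_step_czt(field, zr, n, distance, output_pitch,
                                output_shape, output_center, keep_carrier)
    return _talanov_hop(field, zr, n, distance, output_pitch, output_shape,
                        output_center, keep_carrier)


def _chirped_product_resolved(field, a_chirp) -> bool:
    """True when the single-step integrand V * exp(i pi a r^2 / lam) is
    adequately sampled (e.g. a lens phase stored in V cancels the kernel
    chirp).  Measured, not assumed: the largest phase step between adjacent
    significant samples must stay well below pi."""
    lam = field.wavelength_mm
    xx, yy = field.grid()
    W = field.amplitude * np.exp(1j * np.pi * a_chirp * (xx**2 + yy**2) / lam)
    aw = np.abs(W)
    sig = aw > 1e-3 * aw.max()
    ok = True
    for ax in (0, 1):
        d = W.take(range(1, W.shape[ax]), axis=ax) \
            * np.conj(W.take(range(W.shape[ax] - 1), axis=ax))
        both = sig.take(range(1, W.shape[ax]), axis=ax) \
            & sig.take(range(W.shape[ax] - 1), axis=ax)
        if both.any():
            ok &= bool(np.abs(np.angle(d[both])).max() < 0.9 * np.pi)
    return ok


def _single_step_czt(field, zr, n, distance, output_pitch, output_shape,
                     output_center, keep_carrier):
    lam = field.wavelength_mm
    C = field.carrier_curvature
    xx, yy = field.grid()
    a_chirp = 1.0 / zr - C
    V = field.amplitude * np.exp(1j * np.pi * a_chirp * (xx ** 2 + yy ** 2) / lam)
    scale = lam * zr
    out = _scaled_ft(V, (field.pitch_x, field.pitch_y),
                     (output_pitch, output_pitch), output_shape, scale,
                     center_in=(field.center_x, field.center_y),
                     center_out=output_center)
    out = out / (1j * scale)
    nyo, nxo = output_shape
    x2 = (np.arange(nxo) - nxo // 2) * output_pitch + output_center[0]
    y2 = (np.arange(nyo) - nyo // 2) * output_pitch + output_center[1]
    r2 = x2[np.newaxis, :] ** 2 + y2[:, np.newaxis] ** 2
    C2 = 1.0 / zr
    if not keep_carrier:
        # materialize: chirp must be resolvable at the output pitch
        fmax = C2 * (np.abs(x2).max() + np.abs(y2).max()) / lam
        if fmax > 0.5 / output_pitch:
            raise ValueError("requested output window unresolvable at this pitch; "
                             "keep the carrier or refine output_pitch")
        out = out * np.exp(1j * np.pi * r2 / (lam * zr))
        C2 = 0.0
    out = out * np.exp(2j * np.pi * distance * n / lam)
    return ComplexField(out, output_pitch, output_pitch, field.wavelength,
                        medium_index=n, z=field.z + distance,
                        carrier_curvature=C2,
                        center_x=output_center[0], center_y=output_center[1])


def _talanov_hop(field, zr, n, distance, output_pitch, output_shape,
                 output_center, keep_carrier):
    if output_shape != field.shape or output_center != (0.0, 0.0) \
            or abs(field.center_x) + abs(field.center_y) > 0:
        raise ValueError("Talanov hop keeps the grid shape and centering; "
                         "request matching output_shape/center")
    if field.pitch_x != field.pitch_y:
        raise ValueError("Talanov hop requires square pixels")
    lam = field.wavelength_mm
    M = output_pitch / field.pitch_x
    if not 0 < M:
        raise ValueError("invalid magnification")
    C_star = (1.0 - M) / zr           # carrier that yields this magnification
    C = field.carrier_curvature
    xx, yy = field.grid()
    r2 = xx ** 2 + yy ** 2
    # re-reference the residual from carrier C to carrier C_star
    dC = C_star - C
    fmax = abs(dC) * (abs(field.x()).max() + abs(field.y()).max()) / lam
    if fmax > 0.5 / field.pitch_x:
        raise ValueError("requested output window unresolvable at given grid size: "
                         "carrier re-reference would alias")
    V = field.amplitude * np.exp(1j * np.pi * dC * r2 / lam)
    z_eff = zr / M
    H = _asm_transfer(field.shape, field.pitch_x, field.pitch_y, lam, z_eff)
    V2 = np.fft.ifft2(np.fft.fft2(V) * H) / M
    C2 = C_star / M
    out = ComplexField(V2, output_pitch, output_pitch, field.wavelength,
                       medium_index=n, z=field.z + distance,
                       carrier_curvature=C2)
    out.amplitude *= np.exp(2j * np.pi * distance * n / lam)
    if not keep_carrier and C2 != 0.0:
        xx2, yy2 = out.grid()
        fmax = abs(C2) * (abs(out.x()).max() + abs(out.y()).max()) / lam
        if fmax > 0.5 / output_pitch:
            raise ValueError("requested output window unresolvable: carrier "
                             "cannot be materialized at this pitch")
        out.amplitude = out.amplitude * np.exp(
            -1j * np.pi * C2 * (xx2 ** 2 + yy2 ** 2) / lam)
        out.carrier_curvature = 0.0
    return out


# ---------------------------------------------------------------------------
# thin elements
# ---------------------------------------------------------------------------

def apply_aperture(field: ComplexField, diameter: float,
                   center: tuple[float, float] = (0.0, 0.0),
                   antialias: bool = True) -> ComplexField:
    """Hard-edged circular aperture; optional 1-sample gray-edge anti-aliasing."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    xx, yy = field.grid()
    r = np.sqrt((xx - center[0]) ** 2 + (yy - center[1]) ** 2)
    R = diameter / 2.0
    if antialias:
        edge = max(field.pitch_x, field.pitch_y)
        t = np.clip((R - r) / edge + 0.5, 0.0, 1.0)
    else:
        t = (r <= R).astype(float)
    return replace(field, amplitude=field.amplitude * t)


def apply_phase_mask(field: ComplexField, opd: OPDMap) -> ComplexField:
    """Multiply by exp(i*2*pi*OPD/lambda); NaN OPD samples are opaque."""
    if opd.opd.shape != field.shape:
        raise ValueError(f"OPD grid {opd.opd.shape} does not match field grid "
                         f"{field.shape}")
    if abs(opd.pitch - field.pitch_x) > 1e-12 * field.pitch_x:
        raise ValueError("OPD pitch does not match field pitch")
    lam_um = field.wavelength * 1e-3
    vals = opd.opd
    opaque = ~np.isfinite(vals)
    phase = np.exp(2j * np.pi * np.where(opaque, 0.0, vals) / lam_um)
    amp = field.amplitude * np.where(opaque, 0.0, phase)
    return replace(field, amplitude=amp)


def absorb_parabolic_phase(field: ComplexField, power: float) -> ComplexField:
    """Apply an ideal (aberration-free) thin lens of reduced power ``power``
    (1/mm) entirely into the carrier: the stored residual is untouched and
    the carrier curvature increases by ``power``."""
    return replace(field, amplitude=field.amplitude.copy(),
                   carrier_curvature=field.carrier_curvature + power)


def pupil_to_focus(pupil_amplitude: np.ndarray, pitch: float, wavelength: float,
                   zr: float, output_pitch: float, output_shape: tuple[int, int],
                   output_center: tuple[float, float] = (0.0, 0.0),
                   defocus: float = 0.0) -> np.ndarray:
    """Shared focal-field kernel for the field and ray engines.

    ``pupil_amplitude`` is the sphere-referenced pupil function (amplitude x
    exp(i*phase of the residual aberration)) at a pupil plane a reduced
    distance ``zr`` (mm) before the reference focus; ``defocus`` displaces the
    evaluation plane by a reduced distance (mm).  Returns the complex field on
    the output grid, with the 1/(i*lambda*z) Fresnel normalization so peak
    intensities are comparable across nearby planes.
    """
    lam = wavelength * 1e-6
    z2 = zr + defocus
    ny, nx = pupil_amplitude.shape
    x = (np.arange(nx) - nx // 2) * pitch
    y = (np.arange(ny) - ny // 2) * pitch
    r2 = x[np.newaxis, :] ** 2 + y[:, np.newaxis] ** 2
    a_chirp = 1.0 / z2 - 1.0 / zr
    V = pupil_amplitude * np.exp(1j * np.pi * a_chirp * r2 / lam)
    scale = lam * z2
    out = _scaled_ft(V, (pitch, pitch), (output_pitch, output_pitch),
                     output_shape, scale, center_out=output_center)
    return out / (1j * scale)
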