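"""Image-quality metrics: PSF, Strehl ratio, MTF, Zernike decomposition.

Zernike coefficients use the OSA/ANSI double-index convention over the unit
disk scaled to the stated aperture, reported in micrometres; Z(4,0) is the
coefficient of sqrt(5)(6 rho^4 - 6 rho^2 + 1) — primary spherical aberration.
The Strehl ratio is peak-intensity based, normalized against the same bench
rebuilt from ideal (aberration-free) phase elements of identical paraxial
powers, which cancels windowing and aperture-diffraction effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .field_core import OPDMap

__all__ = ["MetricsResult", "zernike_polynomial", "zernike_fit", "strehl",
           "mtf_from_psf", "osa_index_pairs"]


@dataclass
class MetricsResult:
    """Bundle of image-quality outputs for one bench pose."""
    psf: np.ndarray | None = None
    psf_pitch_um: float | None = None
    strehl: float | None = None
    mtf: pd.DataFrame | None = None
    zernike: pd.DataFrame | None = None
    image: np.ndarray | None = None


def osa_index_pairs(max_order: int):
    """(n, m) pairs for all radial orders up to ``max_order``, OSA ordering."""
    pairs = []
    for n in range(max_order + 1):
        for m in range(-n, n + 1, 2):
            pairs.append((n, m))
    return pairs


def _radial(n, m, rho):
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)
             / (factorial(k) * factorial((n + m) // 2 - k)
                * factorial((n - m) // 2 - k)))
        out = out + c * rho ** (n - 2 * k)
    return out


def zernike_polynomial(n: int, m: int, rho, theta):
    """OSA/ANSI-normalized Zernike polynomial on the unit disk."""
    if (n - abs(m)) % 2 or abs(m) > n:
        raise ValueError("invalid (n, m)")
    N = np.sqrt(2.0 * (n + 1)) if m != 0 else np.sqrt(n + 1.0)
    R = _radial(n, m, np.asarray(rho, dtype=float))
    if m > 0:
        return N * R * np.cos(m * np.asarray(theta))
    if m < 0:
        return N * R * np.sin(-m * np.asarray(theta))
    return N * R


def zernike_fit(opd: OPDMap, aperture_diameter: float | None = None,
                max_order: int = 6) -> pd.DataFrame:
    """Least-squares OSA Zernike fit of an OPD map over ``aperture_diameter``.

    Returns a DataFrame with columns (n, m, coefficient_um).  Requires the
    map to be defined over at least 95% of the fit zone.
    """
    if aperture_diameter is None:
        aperture_diameter = opd.aperture_diameter
    a = aperture_diameter / 2.0
    xx, yy = np.meshgrid(opd.x() - opd.center_x, opd.y() - opd.center_y)
    rho = np.hypot(xx, yy) / a
    theta = np.arctan2(yy, xx)
    zone = rho <= 1.0
    vals = opd.opd
    good = zone & np.isfinite(vals)
    if good.sum() < 0.95 * zone.sum():
        raise ValueError("OPD map undefined over more than 5% of the fit zone")
    pairs = osa_index_pairs(max_order)
    A = np.stack([zernike_polynomial(n, m, rho[good], theta[good])
                  for (n, m) in pairs], axis=1)
    coef, *_ = np.linalg.lstsq(A, vals[good], rcond=None)
    if np.linalg.matrix_rank(A) < len(pairs):
        raise ValueError("rank-deficient Zernike sampling")
    return pd.DataFrame({"n": [p[0] for p in pairs],
                         "m": [p[1] for p in pairs],
                         "coefficient_um": coef})


def zernike_coefficient(table: pd.DataFrame, n: int, m: int) -> float:
    row = table[(table.n == n) & (table.m == m)]
    if row.empty:
        raise KeyError(f"Z({n},{m}) not in table")
    return float(row.coefficient_um.iloc[0])


def strehl(psf: np.ndarray, reference_psf: np.ndarray,
           pitch_um: float | None = None,
           reference_pitch_um: float | None = None) -> float:
    """Peak-intensity Strehl ratio of ``psf`` against the ideal-bench PSF.

    Both rasters must share pitch and input-power normalization."""
    if pitch_um is not None and reference_pitch_um is not None:
        if abs(pitch_um - reference_pitch_um) > 1e-9 * pitch_um:
            raise ValueError("PSF and reference pitches differ")
    ratio = float(psf.max() / reference_psf.max())
    if not 0.0 < ratio <= 1.02:
        raise ValueError(f"Strehl {ratio:.3f} outside (0, 1.02]; check "
                         "normalization of the two rasters")
    return ratio


def mtf_from_psf(psf: np.ndarray, pitch_um: float) -> pd.DataFrame:
    """MTF = |FT of the PSF| normalized to 1 at zero frequency.

    Returns a tidy table: frequency_cpmm, mtf_x (cross-section along the x
    frequency axis, the tangential analogue for y-misalignments), mtf_y.
    """
    otf = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(psf)))
    mtf2 = np.abs(otf)
    ny, nx = psf.shape
    mtf2 = mtf2 / mtf2[ny // 2, nx // 2]
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=pitch_um * 1e-3))
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=pitch_um * 1e-3))
    sel = fx >= 0
    return pd.DataFrame({"frequency_cpmm": fx[sel],
                         "mtf_x": mtf2[ny // 2, sel],
                         "mtf_y": mtf2[sel, nx // 2]})


def diffraction_limited_mtf(freq_cpmm, cutoff_cpmm):
    """Closed-form incoherent MTF of an aberration-free circular pupil."""
    nu = np.clip(np.asarray(freq_cpmm, dtype=float) / cutoff_cpmm, 0.0, 1.0)
    phi = np.arccos(nu)
    return (2.0 / np.pi) * (phi - np.cos(phi) * np.sin(phi))


# ---------------------------------------------------------------------------
# bench-level wrappers (field and ray engines)
# ---------------------------------------------------------------------------

def compute_field_psf(bench, screen_z=None, grid_n=None, psf_n=None):
    """Field-traced PSF of the bench: plane-wave input (mask removed),
    angular-spectrum chain, chirp-z focusing onto the fixed screen.

    Returns (psf, info).  Raises if the diffraction core would span fewer
    than 16 samples at the configured PSF pitch.
    """
    from .eye_model import field_psf
    c = bench.config
    zr = bench.screen_zr(screen_z)
    core_diameter_um = 2 * 1.22 * c.wavelength_nm * 1e-6 * zr \
        / c.pupil_diameter * 1e3
    if core_diameter_um / c.psf_pitch_um < 16:
        raise ValueError(
            f"PSF core (~{core_diameter_um:.2f} um) undersampled at "
            f"{c.psf_pitch_um} um/px; use psf_pitch_um <= "
            f"{core_diameter_um / 16:.3f}")
    return field_psf(bench, screen_z=screen_z, grid_n=grid_n, psf_n=psf_n)


def simulate_image(bench, target, engine="field", image_n=1024,
                   grid_n=None, n_rings=64):
    """Image of a transmission target on the screen.

    ``engine='field'``: full coherent propagation of the masked field
    (shows interference fringes inside the bright bars).
    ``engine='ray'``: ideal demagnified target convolved with the
    ray-traced PSF (incoherent, fringe-free).

    The screen sits at the paraxial conjugate of the mask plane (the bench
    operator's focus for imaging); PSF/Strehl runs use the focal plane
    instead.  Returns (image, info dict with pitch_um, magnification).
    """
    from .eye_model import field_at_exit, mask_conjugate, predicted_image_center
    from . import field_core as fc
    import numpy as np
    c = bench.config
    screen_conj, mag = mask_conjugate(bench)
    zr_conj = (screen_conj - bench.z_ref) / c.n_aqueous
    extent = max(target.extent) * abs(mag) * 1.15
    pitch = extent / image_n
    if engine == "field":
        from .eye_model import _corrected_pupil
        exit_field = field_at_exit(bench, mask=target, grid_n=grid_n)
        pupil = _corrected_pupil(bench, exit_field)
        C = exit_field.carrier_curvature
        fld = fc.pupil_to_focus(pupil, exit_field.pitch_x, c.wavelength_nm,
                                zr=1.0 / C, output_pitch=pitch,
                                output_shape=(image_n, image_n),
                                defocus=zr_conj - 1.0 / C)
        img = np.abs(fld) ** 2
    elif engine == "ray":
        from .raytrace import exit_pupil_opd, psf_from_pupil, \
            ray_image_simulation, trace_bundle
        bundle = trace_bundle(bench, n_rings=n_rings, object_z=bench.z_mask)
        opd = exit_pupil_opd(bundle, (0.0, 0.0, screen_conj), c.n_aqueous,
                             grid_n=min(c.grid_n, 256))
        # PSF kernel on the image grid pitch so the convolution scales match
        psf = psf_from_pupil(opd, c.wavelength_nm, zr_conj, pitch,
                             (129, 129), normalize=False)
        img = ray_image_simulation(bench, target, psf, pitch,
                                   (image_n, image_n), mag)
    else:
        raise ValueError("engine must be 'field' or 'ray'")
    return img, dict(pitch_um=pitch * 1e3, magnification=mag,
                     screen_z=screen_conj)
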