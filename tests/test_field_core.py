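"""Diffraction-engine unit tests: ASM against closed forms and a brute-force
Rayleigh-Sommerfeld quadrature, energy/unitarity properties, chirp-z scaled
propagation against the Airy pattern, thin-element operations."""

import numpy as np
import pytest

from iolbench.field_core import (ComplexField, OPDMap, apply_aperture,
                                 apply_phase_mask, propagate_angular_spectrum,
                                 propagate_scaled, _scaled_ft)

LAM = 543.5            # nm
LAM_MM = LAM * 1e-6


def make_field(amp, pitch):
    return ComplexField(np.asarray(amp, dtype=complex), pitch, pitch, LAM)


def grid(n, pitch):
    x = (np.arange(n) - n // 2) * pitch
    return np.meshgrid(x, x)


class TestAngularSpectrum:
    def test_zero_distance_is_identity(self):
        xx, yy = grid(64, 0.01)
        f = make_field(np.exp(-(xx**2 + yy**2) / 0.01), 0.01)
        g = propagate_angular_spectrum(f, 0.0)
        np.testing.assert_allclose(g.amplitude, f.amplitude, atol=1e-12)

    def test_gaussian_beam_width_law(self):
        """1/e^2 radius after 200 mm matches w(z) = w0 sqrt(1+(z lam/pi w0^2)^2)."""
        w0, z, n = 0.5, 200.0, 1024
        pitch = 8e-3
        xx, yy = grid(n, pitch)
        f = make_field(np.exp(-(xx**2 + yy**2) / w0**2), pitch)
        g = propagate_angular_spectrum(f, z)
        I = g.intensity()
        wz = w0 * np.sqrt(1 + (z * LAM_MM / (np.pi * w0**2))**2)
        w_meas = np.sqrt(2 * np.sum(I * (xx**2 + yy**2)) / np.sum(I))
        assert abs(w_meas - wz) / wz < 0.01

    def test_matches_brute_force_rayleigh_sommerfeld(self):
        """ASM equals a direct RS-I quadrature on a 64x64 grid to < 1e-3.

        The comparison regime is chosen so the quadrature itself converges
        on 64^2 samples: a smooth (Gaussian) aperture field and a distance
        at which the RS kernel stays below the grid Nyquist over the window.
        """
        n, pitch, z, w0 = 64, 0.01, 33.0, 0.07
        x = (np.arange(n) - n // 2) * pitch
        xx, yy = np.meshgrid(x, x)
        amp = np.exp(-(xx**2 + yy**2) / (2 * w0**2))
        f = make_field(amp, pitch)
        g = propagate_angular_spectrum(f, z)
        k = 2 * np.pi / LAM_MM
        U = np.zeros((n, n), complex)
        for iy in range(n):
            for ix in range(n):
                dx = x[ix] - xx
                dy = x[iy] - yy
                r = np.sqrt(dx * dx + dy * dy + z * z)
                kern = (1 / (2 * np.pi)) * (1 / r - 1j * k) * (z / r) \
                    * np.exp(1j * k * r) / r
                U[iy, ix] = np.sum(amp * kern) * pitch * pitch
        dev = np.abs(g.amplitude - U).max() / np.abs(U).max()
        assert dev < 1e-3

    def test_unitarity_forward_backward(self):
        """Propagating +z then -z restores a band-limited field to < 1e-6."""
        n, pitch = 128, 0.01
        xx, yy = grid(n, pitch)
        f = make_field(np.exp(-(xx**2 + yy**2) / (2 * 0.1**2)), pitch)
        g = propagate_angular_spectrum(propagate_angular_spectrum(f, 5.0), -5.0)
        err = np.abs(g.amplitude - f.amplitude).max() / np.abs(f.amplitude).max()
        assert err < 1e-6

    @pytest.mark.parametrize("distance", [1.0, 5.0, 25.0])
    def test_power_never_increases(self, distance):
        n, pitch = 128, 0.01
        xx, yy = grid(n, pitch)
        f = make_field(((xx**2 + yy**2) <= 0.25**2).astype(float), pitch)
        g = propagate_angular_spectrum(f, distance)
        assert g.power() <= f.power() * (1 + 1e-12)

    def test_nonfinite_distance_rejected(self):
        f = make_field(np.ones((8, 8)), 0.01)
        with pytest.raises(ValueError):
            propagate_angular_spectrum(f, np.nan)

    def test_grid_too_small_for_band_limit(self):
        f = make_field(np.ones((16, 16)), 0.005)
        with pytest.raises(ValueError, match="samples"):
            propagate_angular_spectrum(f, 5000.0)


class TestScaledPropagation:
    def test_degenerate_pitch_matches_asm(self):
        n, pitch = 128, 0.01
        xx, yy = grid(n, pitch)
        f = make_field(np.exp(-(xx**2 + yy**2) / (2 * 0.1**2)), pitch)
        a = propagate_angular_spectrum(f, 8.0)
        b = propagate_scaled(f, 8.0, output_pitch=pitch)
        # global phase conventions may differ; compare intensity-normalized
        phase = np.sum(a.amplitude * np.conj(b.amplitude))
        phase /= abs(phase)
        dev = np.abs(a.amplitude - b.amplitude * phase).max() \
            / np.abs(a.amplitude).max()
        assert dev < 1e-3

    def test_airy_first_zero(self):
        """Focal field of an f=50 mm lens with a 1-mm pupil: first null at
        1.22 lam f / D within one output sample."""
        n, pitch, fl, D = 1024, 2.0 / 1024, 50.0, 1.0
        xx, yy = grid(n, pitch)
        r2 = xx**2 + yy**2
        amp = np.where(r2 <= (D / 2)**2,
                       np.exp(-1j * np.pi * r2 / (LAM_MM * fl)), 0)
        f = make_field(amp, pitch)
        out = propagate_scaled(f, fl, output_pitch=1e-3,
                               output_shape=(256, 256))
        row = out.intensity()[128]
        from scipy.signal import argrelmin
        i0 = argrelmin(row[128:])[0][0]
        expected = 1.22 * LAM_MM * fl / D
        assert abs(i0 * 1e-3 - expected) <= 1e-3

    def test_power_bound(self):
        n, pitch = 256, 0.01
        xx, yy = grid(n, pitch)
        r2 = xx**2 + yy**2
        amp = np.where(r2 <= 0.5**2, np.exp(-1j * np.pi * r2 / (LAM_MM * 50)), 0)
        f = make_field(amp, pitch)
        out = propagate_scaled(f, 50.0, output_pitch=2e-3,
                               output_shape=(256, 256))
        assert out.power() <= f.power() * (1 + 1e-6)

    def test_scaled_ft_matches_direct_sum(self):
        rng = np.random.default_rng(7)
        n1, n2 = 12, 9
        arr = rng.normal(size=(n1, n1)) + 1j * rng.normal(size=(n1, n1))
        p1, p2, scale = 0.13, 0.07, 3.7
        ci, co = (0.21, -0.11), (0.05, 0.33)
        out = _scaled_ft(arr, (p1, p1), (p2, p2), (n2, n2), scale,
                         center_in=ci, center_out=co)
        x1 = (np.arange(n1) - n1 // 2) * p1
        x2 = (np.arange(n2) - n2 // 2) * p2
        brute = np.zeros((n2, n2), complex)
        for my in range(n2):
            for mx in range(n2):
                ph = np.exp(-2j * np.pi * (
                    np.add.outer((x1 + ci[1]) * (x2[my] + co[1]),
                                 (x1 + ci[0]) * (x2[mx] + co[0]))) / scale)
                brute[my, mx] = np.sum(arr * ph) * p1 * p1
        assert np.abs(out - brute).max() / np.abs(brute).max() < 1e-12


class TestThinElements:
    def test_oversized_aperture_is_identity(self):
        xx, yy = grid(64, 0.01)
        f = make_field(np.ones((64, 64)), 0.01)
        g = apply_aperture(f, diameter=10.0)
        np.testing.assert_allclose(g.amplitude, f.amplitude)

    def test_aperture_power_is_area_fraction(self):
        n, pitch = 512, 0.01
        f = make_field(np.ones((n, n)), pitch)
        D = n * pitch / 2
        g = apply_aperture(f, D, antialias=True)
        frac = g.power() / f.power()
        expected = np.pi / 4 * (D / (n * pitch))**2
        # one edge ring of pixels of tolerance
        tol = 2 * np.pi * (D / 2) * pitch / (n * pitch)**2
        assert abs(frac - expected) < tol

    def test_aperture_translation_covariance(self):
        n, pitch = 256, 0.01
        f = make_field(np.ones((n, n)), pitch)
        a = apply_aperture(f, 1.006, center=(0.0, 0.0), antialias=False)
        b = apply_aperture(f, 1.006, center=(0.4, 0.0), antialias=False)
        shift = int(round(0.4 / pitch))
        np.testing.assert_allclose(np.roll(a.amplitude, shift, axis=1),
                                   b.amplitude)

    def test_phase_mask_zero_and_constant(self):
        n, pitch = 64, 0.01
        f = make_field(np.ones((n, n)), pitch)
        zero = OPDMap(np.zeros((n, n)), pitch, 1.0)
        np.testing.assert_allclose(apply_phase_mask(f, zero).amplitude,
                                   f.amplitude)
        const = OPDMap(np.full((n, n), 0.123), pitch, 1.0)
        g = apply_phase_mask(f, const)
        np.testing.assert_allclose(np.abs(g.amplitude), np.abs(f.amplitude))
        ratio = g.amplitude / f.amplitude
        assert np.abs(ratio - ratio[0, 0]).max() < 1e-12

    def test_phase_mask_grid_mismatch(self):
        f = make_field(np.ones((64, 64)), 0.01)
        with pytest.raises(ValueError, match="match"):
            apply_phase_mask(f, OPDMap(np.zeros((32, 32)), 0.01, 1.0))

    def test_thin_lens_phase_focuses_at_f(self):
        """OPD = -r^2/2f applied to a plane wave peaks on-axis at z = f
        (within the depth of focus of the f/37 beam)."""
        n, pitch, fl = 512, 2.0 / 512, 30.0
        xx, yy = grid(n, pitch)
        r2 = xx**2 + yy**2
        opd_um = np.where(r2 <= 0.4**2, -r2 / (2 * fl) * 1e3, np.nan)
        f = apply_phase_mask(make_field(np.ones((n, n)), pitch),
                             OPDMap(opd_um, pitch, 0.8))
        peaks = {}
        for z in np.arange(26.0, 34.5, 0.5):
            out = propagate_scaled(f, z, output_pitch=2e-3,
                                   output_shape=(64, 64))
            peaks[z] = out.intensity().max()
        zbest = max(peaks, key=peaks.get)
        assert abs(zbest - fl) <= 1.5
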