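"""Ray-engine tests: exact tracing through ideal and real elements,
exit-pupil OPD maps, and the pupil-function PSF against closed forms."""

import numpy as np
import pytest

from iolbench.eye_model import _TrainBench, _paraxial_focus_z
from iolbench.field_core import OPDMap
from iolbench.raytrace import (RayBundle, _trace_ideal_lens, exit_pupil_opd,
                               hexapolar_coordinates, psf_from_pupil,
                               trace_bundle)

LAM = 543.5
LAM_UM = LAM * 1e-3


def collimated_bundle(heights):
    N = len(heights)
    pos = np.zeros((N, 3))
    pos[:, 1] = heights
    dirs = np.tile([0.0, 0.0, 1.0], (N, 1))
    coords = np.zeros((N, 2))
    coords[:, 1] = heights / max(abs(heights.max()), 1.0)
    return RayBundle(pos, dirs, np.zeros(N), np.ones(N, bool), coords)


class TestBundles:
    def test_hexapolar_layout(self):
        c = hexapolar_coordinates(4)
        assert len(c) == 1 + 6 + 12 + 18 + 24
        assert np.hypot(c[:, 0], c[:, 1]).max() <= 1 + 1e-12

    def test_ideal_lens_focuses_paraxial_rays(self):
        """Collimated rays through an ideal thin lens cross the axis at f."""
        P = 0.02                                  # 20 D, f = 50 mm reduced
        heights = np.array([1e-6, 2e-6, 5e-6])
        b = collimated_bundle(heights)
        _trace_ideal_lens(b, P, 0.0, 1.0, 1.0)
        t_cross = -b.positions[:, 1] / b.directions[:, 1]
        np.testing.assert_allclose(t_cross * b.directions[:, 2], 1.0 / P,
                                   atol=1e-9)


class TestBenchTrace:
    def test_marginal_and_chief_geometry(self, bench):
        """The traced footprint at the exit plane matches the paraxial
        5-mm design pupil scaled to the reference plane."""
        bundle = trace_bundle(bench, n_rings=16)
        assert bundle.n_alive == len(bundle.alive)
        # paraxial footprint at the IOL plane is the design pupil
        from iolbench.eye_model import marginal_ray_height_at_iol
        assert abs(2 * marginal_ray_height_at_iol(bench)
                   - bench.config.pupil_diameter) < 1e-9

    def test_no_ray_loss_at_800um_decenter(self, bench):
        from iolbench.eye_model import set_misalignment
        posed = set_misalignment(bench, 800.0, 0.0)
        bundle = trace_bundle(posed, n_rings=16)
        assert bundle.n_alive == len(bundle.alive)

    def test_ray_density_convergence(self, bench):
        """Doubling the ray density changes the RMS exit OPD by < 1%."""
        focus = (0.0, 0.0, _paraxial_focus_z(bench))
        rms = []
        for rings in (16, 32):
            bundle = trace_bundle(bench, n_rings=rings)
            opd = exit_pupil_opd(bundle, focus, 1.336)
            vals = opd.opd[np.isfinite(opd.opd)]
            rms.append(np.sqrt(np.mean((vals - vals.mean())**2)))
        assert abs(rms[1] - rms[0]) / max(rms[0], 1e-9) < 0.01 \
            or abs(rms[1] - rms[0]) < 1e-3

    def test_aberration_free_lens_is_stigmatic(self):
        """Ideal f/50 thin lens: sphere-referenced exit OPD < lambda/1000 RMS."""
        P = 0.02                                 # f = 50 mm
        coords = hexapolar_coordinates(10)
        N = len(coords)
        pos = np.zeros((N, 3))
        pos[:, :2] = coords * 0.5                # 1-mm pupil
        b = RayBundle(pos, np.tile([0.0, 0.0, 1.0], (N, 1)),
                      np.zeros(N), np.ones(N, bool), coords)
        _trace_ideal_lens(b, P, 0.0, 1.0, 1.0)
        opd = exit_pupil_opd(b, (0.0, 0.0, 50.0), 1.0)
        vals = opd.opd[np.isfinite(opd.opd)]
        rms = np.sqrt(np.mean((vals - vals.mean())**2))
        assert rms < LAM_UM / 1000


def circular_opd(n=128, fill=0.9, phase_fn=None):
    """5-mm circular pupil OPD map on an OPDMap-convention grid."""
    pitch = 5.0 / (n * fill)
    x = (np.arange(n) - n // 2) * pitch
    xx, yy = np.meshgrid(x, x)
    rho = np.hypot(xx, yy) / 2.5
    vals = np.where(rho <= 1.0,
                    phase_fn(rho) if phase_fn else 0.0, np.nan)
    return OPDMap(vals * np.ones_like(rho), pitch=pitch,
                  aperture_diameter=5.0)


class TestPupilPSF:
    ZR = 10.0       # reduced pupil-focus distance, mm

    def test_zero_opd_peak_is_one(self):
        opd = circular_opd()
        psf = psf_from_pupil(opd, LAM, self.ZR, 0.2e-3, (64, 64))
        assert abs(psf.max() - 1.0) < 1e-9

    def test_defocus_matches_extended_marechal(self):
        """sigma = 0.05 and 0.1 waves of defocus: peak within 5% of
        exp(-(2 pi sigma)^2)."""
        for sigma_waves in (0.05, 0.1):
            c20 = sigma_waves * LAM_UM           # Z20 coeff = RMS
            opd = circular_opd(
                phase_fn=lambda rho: c20 * np.sqrt(3) * (2 * rho**2 - 1))
            psf = psf_from_pupil(opd, LAM, self.ZR, 0.2e-3, (128, 128))
            expected = np.exp(-(2 * np.pi * sigma_waves)**2)
            assert abs(psf.max() - expected) / expected < 0.05

    def test_airy_first_zero_location(self):
        opd = circular_opd(n=192)
        pitch_out = 0.1e-3
        psf = psf_from_pupil(opd, LAM, self.ZR, pitch_out, (192, 192))
        row = psf[96]
        from scipy.signal import argrelmin
        i0 = argrelmin(row[96:])[0][0]
        expected = 1.22 * LAM * 1e-6 * self.ZR / 5.0
        assert abs(i0 * pitch_out - expected) <= pitch_out
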