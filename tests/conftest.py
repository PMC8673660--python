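import numpy as np
import pytest

from iolbench.eye_model import (BenchConfig, build_bench, find_focal_plane,
                                reference_psf)

TEST_GRID = 1024


@pytest.fixture(scope="session")
def bench():
    """Calibrated, focused default bench at the test grid resolution."""
    cfg = BenchConfig(grid_n=TEST_GRID)
    b = build_bench(cfg)
    find_focal_plane(b)
    return b


@pytest.fixture(scope="session")
def ref_psf(bench):
    """Ideal-phase-element reference PSF (Strehl denominator)."""
    psf, info = reference_psf(bench)
    return psf


@pytest.fixture(scope="session")
def bench_uncalibrated():
    cfg = BenchConfig(grid_n=TEST_GRID)
    return build_bench(cfg, calibrate_asphere=False)
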