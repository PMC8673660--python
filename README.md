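# iolbench

Coherent field-tracing simulation of an optical test bench for intraocular
lenses (IOLs), with a geometric ray-tracing comparator.

## The problem

After cataract surgery the implanted IOL is rarely perfectly centered: typical
decentrations are a few hundred micrometres and tilts a few degrees. Optical
bench tests quantify what this does to image quality, but physical benches are
slow and expensive, and conventional lens-design software treats light as rays,
which misses interference and diffraction — exactly the effects a coherent
laser bench produces. `iolbench` simulates such a bench twice over, from the
same prescription:

* a **field engine** that propagates a sampled complex scalar field
  (543.5 nm, fully coherent) between the bench planes with the
  angular-spectrum (spectrum-of-plane-waves) method, and
* a **ray engine** that traces exact rays (vector Snell refraction at conic
  aspheric surfaces, rigid-body lens pose) and evaluates the ZEMAX-style
  pupil-function PSF.

The bench: collimated laser → USAF-1951 object mask → 9.072-mm aperture stop
→ single-surface aspheric model cornea (43 D into aqueous, conic constant
Q = −0.26, spherical aberration Z(4,0) = +0.17 µm over a 6-mm zone) → water
cell with plane BK7 windows → 20 D acrylate (n = 1.47) SA-correcting IOL that
can be decentered along y or tilted about y → screen. The stop-to-pupil
spacing, the IOL's front-surface asphere (a₄, a₆ nulling the system's
exit-pupil Z(4,0) and Z(6,0)), and the focal screen position are all found by
calibration; every resolved value is written to a provenance block.

Outputs: retinal image rasters, PSFs, peak-intensity Strehl ratios
S = I_peak / I_peak^ideal (normalized against the same bench rebuilt from
aberration-free phase elements), MTF curves (modulus of the Fourier transform
of the PSF, cycles/mm), and OSA/ANSI Zernike coefficient tables.

## Worked example

```python
from iolbench import (BenchConfig, build_bench, find_focal_plane,
                      field_psf, ray_psf, reference_psf, set_misalignment,
                      strehl)

bench = build_bench(BenchConfig(grid_n=1024))   # calibrates IOL radius + asphere
find_focal_plane(bench)                         # fixes the screen
ref, _ = reference_psf(bench)                   # ideal-bench Strehl reference

for tilt in (0, 2, 4, 6, 8):
    psf, _ = field_psf(set_misalignment(bench, 0.0, tilt))
    rpsf, _ = ray_psf(set_misalignment(bench, 0.0, tilt))
    print(f"tilt {tilt} deg: field Strehl {strehl(psf, ref):.3f}, "
          f"ray Strehl {rpsf.max():.3f}")
```

prints

```
tilt 0 deg: field Strehl 0.936, ray Strehl 0.999
tilt 2 deg: field Strehl 0.776, ray Strehl 0.752
tilt 4 deg: field Strehl 0.345, ray Strehl 0.275
tilt 6 deg: field Strehl 0.204, ray Strehl 0.131
tilt 8 deg: field Strehl 0.127, ray Strehl 0.068
```

The aligned SA-corrected bench is near diffraction limited in both engines and
their MTFs agree to about 0.01; under tilt the Strehl collapses below 0.4 past
4°, and the two engines diverge — the coherent field result degrades
differently from the geometric prediction, which is the point of field
tracing. Decentration is far more damaging in this bench (Strehl < 0.05 by
200 µm) because the calibrated asphere corrects the full 9-mm corneal beam.

From a shell:

```bash
iolbench bench calibrate --out results/
iolbench bench image --engine both --out results/     # fringed vs smooth bars
iolbench sweep decenter --out results/
iolbench sweep tilt --out results/
iolbench report --out results/                        # Strehl curves + MTF panels
```

## Layout

| module | role |
|---|---|
| `field_core` | complex fields, band-limited exact-transfer ASM, chirp-z scaled propagation, thin elements |
| `surfaces` | conic/aspheric surfaces, thick-lens elements, exact refraction, projected OPD maps |
| `raytrace` | hexapolar bundles, exit-pupil OPD, pupil-function PSF, geometric imaging |
| `eye_model` | bench assembly, pupil/asphere/focus calibrations, misalignment poses |
| `targets` | USAF-1951 chart and plane-wave source generation |
| `metrics` | Strehl, MTF, OSA Zernike fits, image simulation |
| `sweeps` | decentration/tilt sweeps, report figures and CSV tables |
| `cli` | `iolbench` command-line entry points |
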