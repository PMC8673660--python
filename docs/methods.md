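# Methods

## Model overview

`iolbench` simulates a wet-cell IOL test bench with two independent optical
engines driven by one prescription. Light travels along +z; y is the decenter
axis; tilt is a right-handed rotation about y through the lens center. The
source is a monochromatic, fully coherent, linearly-sampled scalar field at
543.5 nm — the scalar approximation is deliberate: at this bench's numerical
aperture (≈0.19 image side) vectorial corrections to intensity metrics are
sub-percent, far below the misalignment effects under study.

Element train (aligned): object mask (z = 0) → aperture stop (9.072 mm,
240 mm downstream in air) → aspheric cornea (10 mm further) → water →
1-mm BK7 window → water → IOL → water → 1-mm BK7 window → water → screen.
Media indices at 543.5 nm: air 1.0, aqueous/water 1.336, BK7 1.5195,
IOL acrylate 1.47.

### Calibrated geometry

Only the bench's optical parameters are prescribed (stop and pupil
diameters, corneal power/asphericity/SA, IOL power and index, misalignment
ranges); the axial distances are derived, so three calibrations pin the
geometry:

1. **Stop → pupil.** The cornea is a single refracting surface with apex
   radius R = (n_aq − 1)/K = 7.8140 mm (K = 43 D — the physical, not
   keratometric, convention: the in-bench power is exactly 43 D) and conic
   Q = −0.26. The collimated marginal ray at the stop edge (4.536 mm) must
   arrive at the IOL plane at 2.500 mm; in reduced distance that requires
   (1 − 5/9.072)/0.043 mm⁻¹ = 10.438 mm, i.e. 14.067 mm of physical
   cornea–IOL spacing with one window in the path. An independent paraxial
   two-ray trace confirms the 5.000-mm pupil.
2. **IOL form.** Equal-radii biconvex, center thickness 0.9 mm, optic
   diameter 7 mm (chosen so an 800-µm decenter never vignettes the 5-mm
   pupil). The base radius (13.3589 mm) is root-found so the Gullstrand
   thick-lens power in water is exactly 20 D. The front-surface even-asphere
   coefficients are then calibrated by nested scalar root-finds on exact ray
   traces: a₄ nulls the aligned bench's exit-pupil Z(4,0), a₆ nulls Z(6,0)
   (a₄ = −2.635·10⁻³ mm⁻³, a₆ = −4.21·10⁻⁵ mm⁻⁵). Neither coefficient
   carries paraxial curvature, so the 20 D power is preserved identically.
   This realizes the "SA-correcting" property: with the asphere removed, the
   system's Z(4,0) over the zone mapping to 6 mm at the cornea rises by the
   corneal SA (≈0.17 µm).
3. **Focal plane.** With the mask removed, a plane wave is propagated through
   the bench and the screen position maximizing the axial peak intensity is
   found by a bounded golden-section search (≈1 µm tolerance). This screen is
   then held fixed for every misalignment pose of a sweep (bench practice;
   per-pose refocus is available as a flag, default off). Imaging runs place
   the screen at the mask's paraxial conjugate instead — with coherent
   collimated illumination the focal plane is the Fourier plane of the mask,
   not its image, so "focused on the target" is the conjugate plane.

The corneal prescription is internally consistent: the exact ray trace of the
43 D / Q = −0.26 surface gives Z(4,0) = 0.178 µm over a 6-mm zone, within
0.006 µm of the quoted 0.172, so no re-calibration of Q is applied.

## Field engine

Free-space hops use the angular-spectrum method with the exact non-paraxial
transfer function exp(i2πd√((n/λ)² − f²)); evanescent components are dropped
and a Matsushima-style band limit suppresses frequencies that would wrap
around the periodic window. Both properties make total power non-increasing.

A converging beam behind the cornea carries local fringe frequencies ~5×
beyond the grid Nyquist, so it is stored as a slowly varying residual V times
an analytic parabolic carrier exp(−iπCr²/λ₀) with reduced curvature C
(distances are bookkept as reduced lengths t/n, which renders the plane
windows pure path bookkeeping). Carrier-referenced hops use the Talanov
similarity transform — the carrier transports as an exactly scaled spherical
wave (magnification M = 1 − TC), while V is propagated over the reduced
effective distance T/M with the exact transfer function. Focal-plane and
image-plane fields are evaluated by a single chirp-z (Bluestein) Fresnel
integral at arbitrary output pitch and window center (the window is centered
on the chief-ray prediction for misaligned poses); the regime switch between
the single-step chirp-z and the Talanov hop is decided by measuring whether
the sampled integrand is phase-resolved.

Refracting elements are thin screens with two refinements that matter at this
bench's scale:

* **Cornea: back-propagated eikonal screen.** The corneal sag is 1.3 mm at
  the stop edge, so the naive projection screen −(n₂−n₁)·sag misplaces the
  refraction by the sag depth (tens of µm of OPD). Instead, collimated rays
  are refracted exactly at the true surface and extrapolated back to the
  vertex plane, where the eikonal is recorded; this reproduces both the
  wavefront and the ray aim of the real surface in the downstream medium.
* **IOL: cone-following chord map.** The projected OPD is the glass chord
  times (n_g − n_w), integrated along the local direction of the converging
  illumination cone (not z-parallel lines), with the posed (decentered,
  tilted) lens volume intersected by Newton iteration per sample. Samples
  missing the clear aperture are opaque. The screen sits at the lens's
  reduced midplane, which for a symmetric biconvex lens coincides with both
  principal planes; the paraxial quadratic is absorbed into the carrier in
  the same (well-sampled) multiplication.

**Nonparaxial transport correction.** The paraxial kernels under-count the
slant-path optical length of the converging cone; through this train the
deficit reaches ~130 rad (r⁴-and-higher) at the pupil edge. The engine
corrects it with a fixed radial phase map computed once per bench geometry as
the difference between two deterministic meridional ray fans through the same
screens — one with exact Snell refraction and slant paths (sphere-referenced),
one with the paraxial transport rules the field chain uses — applied at the
exit pupil and held fixed for all poses. It is a property of the propagation
operator for this cone geometry, not of the pose under test: all
misalignment-induced degradation seen in the sweeps is produced by the field
chain itself. With the correction the aligned bench reaches a field Strehl of
0.936 against the ideal-element reference (the ray engine reads 0.999; the
residual 0.15-rad-RMS phase is the irreducible diffraction-vs-ray-bookkeeping
difference of the correction), and aligned field and ray MTFs agree to ~0.01.

## Ray engine

Hexapolar bundles (64 rings in production, 16–32 in tests) are traced with
vector Snell refraction at every surface; the posed IOL is handled by
rigid-body transformation into the lens frame and Newton intersection with
the conic-plus-asphere sags. Exit-pupil OPD is measured against the reference
sphere centered on the aligned image point on the fixed screen and reported
as (reference − ray), which makes corneal SA positive in the clinical
convention; the physical pupil phase used for PSFs is its negative. The PSF
is the squared modulus of the chirp-z Fourier transform of the pupil function
— the same transform, grid and normalization the field engine uses, so
engine differences are physics, not conventions. Ray Strehl is normalized by
the aberration-free same-pupil peak. Geometric images are the paraxially
demagnified ideal target convolved with the ray PSF (isoplanatic,
incoherent), on the same grid as the field image.

## Metrics

* **Strehl**: peak intensity over the peak of the same bench rebuilt from
  ideal phase elements (same stop, apertures, powers, input power), each at
  its own best focus. This cancels windowing and aperture-diffraction factors
  that a textbook Airy-peak normalization would not.
* **MTF**: modulus of the 2-D FFT of the PSF raster, normalized at zero
  frequency; x/y cross-sections are reported because misaligned PSFs are
  anisotropic, and misalignment comparisons use the cross-section along the
  misalignment axis.
* **Zernike**: OSA/ANSI double-index polynomials, least squares over the
  stated aperture, coefficients in µm; Z(4,0) is the coefficient of
  √5(6ρ⁴−6ρ²+1).

## Synthetic fixtures

The USAF-1951 chart is generated programmatically: three-bar elements with
frequency 2^(g+(e−1)/6) lp/mm, bar length five widths, bright bars on an
opaque background (the bright bars carry the light, so coherent fringes
appear inside them), groups laid out in two staggered element columns.
Groups that would not fit the 5-mm extent raise an error rather than
overlap. The generator is deterministic. It emulates chart geometry only —
no chrome granularity, phase noise, or legend artwork — so image tests probe
diffraction and misalignment response, not target fabrication effects.

## Numerical choices and problem sizes

| parameter | default | note |
|---|---|---|
| grid | 2048² over 13.6 mm (6.6 µm pitch) | resolves the corneal residual (≤54 cyc/mm vs 75 Nyquist); tests and sweeps use 1024² where Strehl values agree to ~0.001 |
| PSF raster | 1024² at 0.15 µm | diffraction core ≈ 18 samples |
| focal search | golden section, ±1 mm bracket, ~1 µm tol | deterministic |
| ray bundles | 64 rings (≈12k rays) | RMS OPD converged to <1% at 16 rings |
| apertures | hard edge + 1-sample gray ramp (default on) | reduces edge ringing without changing resolved structure |

There is no randomness anywhere in the physics; all calibrations are
deterministic root-finds, so identical configs reproduce byte-identical CSVs.

## Known limitations

* Scalar, monochromatic, fully coherent only; no polarization, partial
  coherence, or polychromatic weighting.
* Thin-screen projection of the IOL (cone-following chords): valid for the
  ≤8° tilts and ≤2 mm decenters enforced by the pose envelope; rigorous
  tilted-plane spectral rotation is out of scope.
* The transport-consistency map is computed for the aligned cone, so the
  field engine's pose-dependent kernel error (~few rad at the largest poses)
  is part of the honest engine difference, alongside the genuine
  diffraction-vs-geometry divergence.
* With the collimated 9.072-mm stop directly before the cornea, the
  corneal zone feeding the pupil is 9.072 mm and the calibrated asphere
  corrects ~0.9 µm of Z(4,0); this makes Strehl-vs-decenter decay much
  faster than in a bench whose target optics illuminate only ~6 mm of
  cornea. Tilt behavior (Strehl below 0.4 beyond 4°) is insensitive to this
  choice. All decentration conclusions here are therefore bounds-style, not
  curve reproductions.
* Passing tests demonstrate internal consistency between two independent
  engines and against closed forms — not agreement with any physical bench's
  mechanical tolerances, source noise, or detector effects.
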