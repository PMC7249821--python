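# Methods

This note documents the physical model, the numerical choices and the open
design decisions behind `ringpam`, and states what the synthetic phantoms
do and do not show about real measurements.

## Coordinate and unit conventions

All lengths are millimetres, times microseconds, speeds mm/µs (the default
sound speed is 1.5 mm/µs, water-like coupling).  `z = 0` is the plane of
the flat centre ring, z increasing into the sample.  Inclined and curved
elements rise *toward the sample* with radius: for a cone of inclination θ
based at radius `r_base`, the surface elevation is `(r − r_base)·tan θ ≥ 0`.
This orientation is what makes the detectors focus — the distance from an
on-axis source at depth `z = r/tan θ + (r − r_base)·tan θ` to the surface
is stationary in radius, so the wave arrives near-simultaneously across the
element.  With the elements tilted the other way no stationary point
exists and an inclined ring would never focus.

Source amplitudes are relative (arbitrary units) throughout the forward
model; pascals enter only in the sensitivity metrics (SNR → NEP → fluence),
which are algebraic conversions.

## Forward model

The signal of one element is `s(t) = Σᵢ aᵢ·gᵢ(t) ∗ h(rᵢ, t)`, with the
N-wave `g` (antisymmetric, linear within its support `d/cs`, unit
peak-to-peak) used directly as the source wavelet: the temporal derivative
of the underlying wave-equation solution is absorbed into the N shape, so
no numerical differentiation is performed.  Sources are treated as points
in `h`; their finite size enters only through the N-wave duration.

Surfaces are meshed into concentric bands (azimuthal counts even and
half-offset, so the point set is mirror-symmetric and mirrored phantoms
produce exactly mirrored B-scans).  Each band stores its analytic area
(weights sum exactly to the element area) and its on-surface edge
positions.  The retarded contribution of a patch, `weight/|r0 − r|`, is
deposited as a uniform density over the patch's radial arrival-time window
`[min, max]` of the edge/mid distances, *integrated exactly over the time
bins* via a four-splat slope-change scatter and double cumulative sum.
This removes the aliasing between band spacing and time sampling that
plagues point-delta deposition: the on-axis annulus response reproduces the
closed-form plateau `2π·cs` to ~1e-5 at 0.1 mm spacing, and halving the
default 0.25 mm spacing changes simulated signals by ≲ 0.2% (L2, on-axis
sources).  For strongly off-axis sources the azimuthal discretization
dominates and the residual is ~1% at 0.25 mm; use a finer mesh when
absolute off-axis amplitudes matter.

The default time grid is dt = 0.01 µs (100 MHz), ≥ 30 samples across the
0.33 µs N-wave of a 0.5 mm sphere; simulations here use a 4–33 µs window
covering depths 12–40 mm for all bundled geometries.  Noise is additive
white Gaussian per channel with a stated RMS and seed (the RMS noise level
is what the sensitivity analysis measures; no spectral shaping is
modelled).

Not modelled: frequency-dependent element response and electronics,
acoustic attenuation, heterogeneous sound speed, shear waves, reflections,
element cross-talk.

## Focusing-range rating vs. exact focus

`normal_incidence_depth_range` reports the *rating*
`z(r) = r/tan θ − (r − r_base)·tan θ`, the device designers' convention for
the normal-incidence depth of an inclined ring (for the fabricated array's
outermost ring over its etched bounds this gives 32.6 mm, the device's
nominal "about 32 mm" depth limit).  Note this subtracts the element
elevation where the
exact stationary-phase focus of the meshed surface adds it; the rating is
therefore conservative relative to the simulated amplitude maxima.  The
simulation and reconstruction never use the rating — they work from the
exact geometry — so the discrepancy only affects how the depth limit is
quoted.

## Reconstruction

*Model matrices.*  Row k of `M` is the element signal of a 50 µm probe
sphere at depth `z_k` on the axis (50 µm is below the device resolution, so
the rows act as point-spread templates).  Rows are scaled to unit L2 norm —
the stated normalization is open, and unit L2 makes
`a(z) = Σₙ M[k, n] s[n] dt` a matched filter with depth-independent noise
gain, which the sensitivity calibration then corrects for signal strength.
The shared depth grid (default 0.05 mm steps; 12–40 mm here) realizes the
interpolation of all rings onto a common z axis.  Matched-filter A-scans
localize on-axis microspheres to within one depth step across 15–35 mm.

*Coherence factor.*  The standard coherent-power over N×incoherent-power
form, computed from the per-ring A-scans in the depth domain and applied
once after summation; `CF = 0` where the incoherent power vanishes.  The
exact variant (and any exponent) used on real hardware is an open choice;
this one is scale-invariant and bounded in [0, 1].  The envelope (Hilbert
transform along depth) is taken after CF weighting; a `positive` display
mode discards negative values of the combined A-scan before the envelope.

*Two focusing modes.*  `reconstruct_bscan` is the matched-filter pipeline
above.  `tof_focus_bscan` instead interpolates each ring's raw signal from
time to depth through its arrival-time relation (per-depth envelope-peak
time of the model rows) and then sums and CF-weights.  The matched filter
equalizes depth sensitivity by construction, which is what a device
pipeline wants but deliberately hides sensitivity differences; the
time-of-flight mode preserves received amplitudes and is therefore used to
*compare geometries* (e.g. the conical array's on-axis amplitude is ~3–4×
the equal-area planar array's on the five-sphere phantom, and a spherical
cap shows its narrow DOF).

*Preprocessing.*  Mean subtraction along the scan direction removes
scan-position-independent artefacts; a single-position scan is passed
through with a warning since subtraction would annihilate it.

*Calibration.*  For equal-strength on-axis reference targets at known
depths, the weight per depth is the reciprocal of the strongest ring's
A-scan peak, linearly interpolated between depths and clamped outside.
Applying the table to its own reference data flattens the per-depth
sensitivity exactly; this calibrated max-ring profile is also the quantity
on which the depth of field is measured (−6 dB threshold by default, a
declared choice).  The CF-weighted *combined* peak is not flat to a few
percent by construction: the ratio of coherent sum to strongest ring varies
with how many rings focus at a given depth.

## Phantoms

All phantoms are sphere sets.  Extended absorbers (leads, tubes) are
rasterized into chains of spheres of the object diameter at quarter-
diameter spacing (default), with trapezoid-rule per-sphere amplitudes so
the total source strength is exactly spacing-independent; halving the
default spacing changes simulated RF by < 1%.  The canonical microsphere
is 0.1 mm (a single fixed value representative of 90–110 µm resolution
targets).  Tube presets use declared control points; self-intersection is
not checked.

The generators emulate geometry and source strength only: no optical
scattering/fluence distribution inside objects, no acoustic properties of
the embedding gel.  Consequently, passing tests demonstrate the geometry
and reconstruction logic, not absolute experimental resolutions or CNR
values — experimentally measured figures (e.g. 285 µm/95 µm resolution,
CNR of a physical microsphere) depend on bandwidth, electronics and
phantom optics that are outside the model.  Directional properties are the
testable surface: CF raises CNR at the few-percent noise level used in the
tests while changing lateral FWHM by < 10% (under much heavier noise the
CNR gain washes out); single-ring X-crossing ghosts rival true objects
while the CF-weighted combined image suppresses them below half the weaker
object's amplitude.

## Measurement conventions (metrics)

FWHM comes from a least-squares Gaussian fit (amplitude, centre, σ,
offset), `FWHM = 2√(2 ln 2)·σ`, flagged when R² < 0.8.  CNR is
(signal-ROI peak − background mean)/background std — a declared definition,
since the quantity is not standardized; measured values depend on ROI
placement (the bundled analyses use a window around the known target and a
flanking artefact band).  SNR is envelope peak over the RMS of a
signal-free window; NEP = p0/SNR; fluence↔pressure conversion is
`F [mJ/cm²] = p/(Γ·μa[mm⁻¹])·10⁻⁴` (1 Pa ≡ 1 J/m³ absorbed energy
density).

## Problem sizes

Bundled analyses and tests run at desk scale, chosen to keep the full
pipeline comfortably reproducible on one CPU: 0.25 mm surface quadrature,
100 MHz sampling over 4–33 µs, 0.05 mm depth grid over 12–40 mm, scan
ranges of ±3–7 mm at 0.1–0.2 mm increments, and 20 calibration depths.
All of these are parameters; finer settings change results by well under
the tolerances quoted above (see the convergence tests).
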