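# ringpam — conical ring-array scanning photoacoustic macroscopy

`ringpam` is a design and simulation toolkit for scanning photoacoustic
macroscopy (PAM) with axisymmetric focused detectors.  Deeply penetrating
acoustic-resolution PAM images optical absorbers centimetres below the
tissue surface, but a conventional spherically focused detector trades
depth of field (DOF) against lateral resolution: outside its focal zone,
both sensitivity and resolution collapse.  A conical *ring array* — a flat
annular element surrounded by ring elements on an inclined (conical)
substrate — keeps near-normal acoustic incidence on at least one element
over a ~20 mm depth range, and per-ring dynamic focusing with coherence
weighting recovers a sharp on-axis image without the X-shaped artefacts of
single-element axicon detectors.

The package is for transducer designers and photoacoustic-imaging
researchers who want to compare detector geometries (spherical cap, axicon,
planar ring array, conical ring array), simulate multi-channel RF B-scans
of numerical phantoms, and run the full reconstruction pipeline with
quantitative image metrics.

## Model

A spherical absorber of diameter *d* uniformly heated by a short laser
pulse emits a bipolar, antisymmetric N-wave `g(t)` of duration `d/cs`
(initial pressure `p0 = Γ·μa·F` with Grueneisen parameter Γ, absorption
coefficient μa and fluence F).  A finite detector surface *S* receives the
spatial impulse response of a point source at **r**,

    h(r, t) = ∫_S |r0 − r|⁻¹ δ(t − |r0 − r|/cs) dS0 ,

and the channel signal is `s(t) = Σᵢ aᵢ · gᵢ(t) ∗ h(rᵢ, t)`.  Surfaces are
discretized into concentric quadrature bands whose retarded contributions
are integrated exactly over the time bins (alias-free by construction).

Reconstruction builds, per ring, a model matrix `M[k, n] = (g ∗ h)(z_k, t_n)`
for a 50 µm probe source on the symmetry axis; rows are scaled to unit L2
norm, so `a(z_k) = Σₙ M[k, n]·s[n]·dt` is a matched-filter A-scan mapping
arrival time to depth.  A-scans of all rings share one depth grid (the
dynamic focus), are summed, and are weighted by the coherence factor

    CF(z) = (Σᵢ aᵢ(z))² / (N · Σᵢ aᵢ(z)²) ∈ [0, 1],

which suppresses depths where the rings disagree (noise, X-artefact legs).
A reciprocal-of-maximum calibration flattens the device's depth response;
Hilbert envelopes, Gaussian-fit FWHM, CNR, SNR/NEP and −6 dB DOF metrics
quantify the images.

## Worked example

`examples/03_reconstruction_pipeline.py` simulates a noisy B-scan of a
0.1 mm microsphere at 25 mm depth with the fabricated-array measurement
configuration (flat centre ring + three outer 25° rings) and reconstructs
it with and without coherence weighting:

```
dynamic focus only  : peak depth 25.00 mm, CNR  75.2, lateral FWHM   213 µm
with CF weighting   : peak depth 25.00 mm, CNR  82.1, lateral FWHM   209 µm
```

The microsphere localizes exactly on the depth grid; coherence weighting
raises the contrast-to-noise ratio while leaving the lateral resolution
essentially unchanged.  `examples/04_calibration_depth_of_field.py`
continues with the sensitivity calibration:

```
raw profile std/mean:        0.256
calibrated profile std/mean: 2.48e-17
-6 dB depth of field: 20 – 39 mm (extent 19 mm)
```

i.e. the raw per-depth response of the array varies by ~26% over 20–39 mm
and is flat after calibration, giving a ≈ 19 mm depth of field.  The other
examples cover geometry design (`01`), the forward model and its
closed-form impulse-response oracle (`02`), and SNR/NEP/fluence analysis
(`05`).  A thin CLI mirrors the pipeline stages
(`ringpam phantom | simulate | reconstruct | calibrate | metrics | run`).

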