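# Bundled detector geometries.
#
# fabricated_array: the five-element PVDF array — one flat centre ring plus
#   four rings on a 25 degree cone.  Active bounds derive from the etched
#   radii 7.75 / 10.75 / 13.25 / 15.25 / 17.25 mm with the 0.5 mm etched
#   lines insensitive; the cone meets the flat plane at radius 7.75 mm.
#   The flat ring's inner radius (4.0 mm, set by the illumination window)
#   and its outer bound (7.25 mm) are declared assumptions.
#
# The four design-study geometries share a 28 mm outer diameter:
#   spherical_cap_25mm: spherical surface with centre of curvature at 25 mm.
#   axicon_25deg: full cone, 25 degrees to the plane perpendicular to the axis.
#   planar_ring_array: four flat rings of equal area, innermost 3-7 mm
#     (boundaries r_k = sqrt(9 + 40 k)).
#   conical_ring_array: flat 3-7 mm ring plus three 25 degree rings whose
#     areas equal the flat ring's (boundary step r^2 -> r^2 + 40 cos 25deg).

fabricated_array:
  elements:
    - {name: flat_ring, type: flat_ring, r_inner: 4.0, r_outer: 7.25}
    - {name: ring1, type: cone_ring, r_inner: 8.0, r_outer: 10.5, inclination_deg: 25.0, r_base: 7.75}
    - {name: ring2, type: cone_ring, r_inner: 11.0, r_outer: 13.0, inclination_deg: 25.0, r_base: 7.75}
    - {name: ring3, type: cone_ring, r_inner: 13.5, r_outer: 15.0, inclination_deg: 25.0, r_base: 7.75}
    - {name: ring4, type: cone_ring, r_inner: 15.5, r_outer: 17.0, inclination_deg: 25.0, r_base: 7.75}

spherical_cap_25mm:
  elements:
    - {name: cap, type: spherical_cap, radius_of_curvature: 25.0, aperture_diameter: 28.0}

axicon_25deg:
  elements:
    - {name: axicon, type: cone_ring, r_inner: 0.0, r_outer: 14.0, inclination_deg: 25.0, r_base: 0.0}

planar_ring_array:
  elements:
    - {name: p1, type: flat_ring, r_inner: 3.0, r_outer: 7.0}
    - {name: p2, type: flat_ring, r_inner: 7.0, r_outer: 9.4339811321}
    - {name: p3, type: flat_ring, r_inner: 9.4339811321, r_outer: 11.3578166916}
    - {name: p4, type: flat_ring, r_inner: 11.3578166916, r_outer: 13.0}

conical_ring_array:
  elements:
    - {name: c1, type: flat_ring, r_inner: 3.0, r_outer: 7.0}
    - {name: c2, type: cone_ring, r_inner: 7.0, r_outer: 9.2332178292, inclination_deg: 25.0, r_base: 7.0}
    - {name: c3, type: cone_ring, r_inner: 9.2332178292, r_outer: 11.0229135424, inclination_deg: 25.0, r_base: 7.0}
    - {name: c4, type: cone_ring, r_inner: 11.0229135424, r_outer: 12.5601327399, inclination_deg: 25.0, r_base: 7.0}
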