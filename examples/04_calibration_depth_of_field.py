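"""Depth-sensitivity calibration and depth of field.

Simulates equal-strength microspheres at 1 mm steps over 20–39 mm, builds
the reciprocal-of-maximum calibration table and shows that the calibrated
sensitivity profile is flat, giving a −6 dB depth of field of ≈ 19 mm.
"""

import numpy as np

import ringpam as rp
from ringpam.metrics import dof_from_profile
from ringpam.reconstruct import (
    build_model_matrices,
    calibrate_sensitivity,
    sensitivity_profile,
)

CS = 1.5
grid = rp.TimeGrid(4.0, 0.01, 2900)
z = np.arange(12.0, 40.0 + 1e-9, 0.05)
array = rp.measurement_array()
matrices = build_model_matrices(array, z, grid, CS)

depths = np.arange(20.0, 39.0 + 1e-9, 1.0)
scans = [
    rp.simulate_bscan(array, rp.microsphere(d), [0.0], CS, grid) for d in depths
]

raw = sensitivity_profile(scans, depths, matrices)
table = calibrate_sensitivity(scans, depths, matrices)
flat = sensitivity_profile(scans, depths, matrices, table)

print("depth (mm)   raw peak   calibrated")
for d, r, f in zip(depths[::4], raw[::4], flat[::4]):
    print(f"   {d:5.1f}     {r:8.5f}     {f:6.3f}")
print(f"\nraw profile std/mean:        {raw.std()/raw.mean():.3f}")
print(f"calibrated profile std/mean: {flat.std()/flat.mean():.2e}")
dof = dof_from_profile(depths, flat, drop_db=6.0)
print(
    f"-6 dB depth of field: {dof.z_low:.0f} – {dof.z_high:.0f} mm "
    f"(extent {dof.extent:.0f} mm)"
)
print("-> after calibration the device responds uniformly over ~20 mm of depth.")
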