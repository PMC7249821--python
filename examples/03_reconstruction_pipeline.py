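"""Dynamic-focusing reconstruction of a noisy microsphere B-scan.

Simulates a 0.1 mm microsphere at 25 mm depth with seeded noise, builds the
per-ring model matrices, and compares plain dynamic focusing with
coherence-factor (CF) weighting: CF raises the contrast-to-noise ratio
while leaving the lateral resolution essentially unchanged.
"""

import numpy as np

import ringpam as rp
from ringpam.reconstruct import build_model_matrices, reconstruct_bscan

CS = 1.5
grid = rp.TimeGrid(4.0, 0.01, 2900)
z = np.arange(12.0, 40.0 + 1e-9, 0.05)
scan = np.arange(-3.0, 3.0 + 1e-9, 0.1)

array = rp.measurement_array()  # flat centre ring + three outer 25° rings
clean = rp.simulate_bscan(array, rp.microsphere(25.0), scan, CS, grid)
noise = 0.02 * np.abs(clean.data).max()
rf = rp.simulate_bscan(
    array, rp.microsphere(25.0), scan, CS, grid, noise_rms=noise, seed=7
)

matrices = build_model_matrices(array, z, grid, CS)
X, Z = np.meshgrid(scan, z, indexing="ij")
signal_roi = (np.abs(X) <= 0.5) & (np.abs(Z - 25.0) <= 1.0)
background_roi = (np.abs(X) >= 1.0) & (np.abs(Z - 25.0) <= 2.5)

for coherence, label in ((False, "dynamic focus only"), (True, "with CF weighting")):
    img = reconstruct_bscan(rf, matrices, coherence=coherence)
    depth = img.z[np.argmax(img.image[len(scan) // 2])]
    contrast = rp.cnr(img.image, signal_roi, background_roi)
    k = int(np.argmax(img.image[len(scan) // 2]))
    lateral = rp.fwhm(scan, img.image[:, k])
    print(
        f"{label:20s}: peak depth {depth:.2f} mm, CNR {contrast:5.1f}, "
        f"lateral FWHM {lateral:5.0f} µm"
    )
print("-> CF suppresses the incoherent background (noise and X-artefacts)")
print("   without broadening the microsphere image.")
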