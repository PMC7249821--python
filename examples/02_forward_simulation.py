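"""Forward simulation: spatial impulse response and a five-sphere B-scan.

Verifies the quadrature impulse response against the closed-form on-axis
annulus solution (a plateau of height 2π·cs between the edge arrival
times), then simulates a small B-scan of the five-sphere column with the
conical ring array.
"""

import numpy as np

import ringpam as rp

CS = 1.5  # mm/µs
grid = rp.TimeGrid(4.0, 0.01, 2900)

# --- impulse-response oracle: flat annulus 3-7 mm, on-axis source at 20 mm
mesh = rp.surface_mesh(rp.RingElement(3.0, 7.0), 0.1)
h = rp.spatial_impulse_response(mesh, (0, 0, 20.0), CS, grid)
t1, t2 = np.hypot(20, 3) / CS, np.hypot(20, 7) / CS
inner = (grid.t > t1 + 0.03) & (grid.t < t2 - 0.03)
print(f"annulus arrival window: {t1:.3f} – {t2:.3f} µs")
print(f"plateau height: {h[inner].mean():.4f} (closed form 2π·cs = {2*np.pi*CS:.4f})")
print(f"max plateau error: {np.abs(h[inner] - 2*np.pi*CS).max()/(2*np.pi*CS):.2e}")

# --- B-scan of the five-sphere column with the conical four-ring array
array = rp.load_geometry("conical_ring_array")
rf = rp.simulate_bscan(
    array, rp.sphere_column(), np.arange(-2.0, 2.0 + 1e-9, 0.5), CS, grid
)
print(f"\nsimulated RF data: {rf.data.shape} (element × scan × time)")
for i, name in enumerate(rf.element_names):
    s = rf.data[i, len(rf.scan_x) // 2]
    print(
        f"  {name}: peak |s| = {np.abs(s).max():.3f} at "
        f"t = {grid.t[np.argmax(np.abs(s))]:.2f} µs"
    )
print("-> each ring sees the five spheres at its own arrival times; the")
print("   inclined rings receive near-simultaneous (focused) arrivals.")
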