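"""Forward model: N-wave, spatial impulse response, signals and B-scans."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ringpam as rp
from ringpam.forward import TruncationWarning, UndersamplingError

CS = 1.5


class TestNWave:
    def test_antisymmetric_zero_at_center(self, grid):
        g = rp.n_wave(0.5, CS, grid)
        K = g.size // 2
        assert g[K] == 0.0
        assert np.allclose(g, -g[::-1])

    def test_support_duration(self, grid):
        g = rp.n_wave(0.5, CS, grid)
        nz = np.flatnonzero(g)
        support = (nz[-1] - nz[0]) * grid.dt
        assert support == pytest.approx(0.5 / CS, abs=2 * grid.dt)

    def test_unit_peak_to_peak(self, grid):
        g = rp.n_wave(0.5, CS, grid)
        T = 0.5 / CS
        assert g.max() - g.min() == pytest.approx(1.0, abs=2 * grid.dt / T)

    def test_undersampled_pulse_rejected(self, grid):
        with pytest.raises(UndersamplingError):
            rp.n_wave(0.02, CS, grid)  # support 13 ns < 2 dt


class TestSpatialImpulseResponse:
    def test_single_point_mesh(self, grid):
        """One patch of area ΔS at distance d: arrival d/cs, integral ΔS/d."""
        mesh = rp.SurfaceMesh(
            np.array([[0.0, 0.0, 0.0]]), np.array([2.0]), rp.RingElement(3.0, 7.0)
        )
        h = rp.spatial_impulse_response(mesh, (0.0, 0.0, 15.0), CS, grid)
        assert grid.t[np.argmax(h)] == pytest.approx(15.0 / CS, abs=grid.dt)
        assert h.sum() * grid.dt == pytest.approx(2.0 / 15.0, rel=1e-6)

    @pytest.mark.parametrize(
        "z,ri,ro", [(20.0, 3.0, 7.0), (25.0, 4.0, 7.25), (30.0, 5.0, 12.0)]
    )
    def test_on_axis_annulus_plateau_oracle(self, grid, z, ri, ro):
        """Closed form: h = 2π·cs between the edge arrival times, else 0."""
        mesh = rp.surface_mesh(rp.RingElement(ri, ro), 0.1)
        h = rp.spatial_impulse_response(mesh, (0, 0, z), CS, grid)
        t = grid.t
        t1 = np.hypot(z, ri) / CS
        t2 = np.hypot(z, ro) / CS
        inner = (t > t1 + 3 * grid.dt) & (t < t2 - 3 * grid.dt)
        outside = (t < t1 - 3 * grid.dt) | (t > t2 + 3 * grid.dt)
        plateau = 2 * np.pi * CS
        assert np.abs(h[inner] - plateau).max() < 0.01 * plateau
        assert np.abs(h[outside]).max() < 0.01 * plateau

    def test_cap_focus_single_bin(self):
        """All cap points are equidistant from the centre of curvature."""
        cap = rp.SphericalCap(25.0, 28.0)
        mesh = rp.surface_mesh(cap, 0.2)
        t0 = 25.0 / CS
        grid = rp.TimeGrid(t0 - 5 * 0.01, 0.01, 12)
        h = rp.spatial_impulse_response(mesh, (0, 0, 25.0), CS, grid)
        integral = h.sum() * grid.dt
        assert integral == pytest.approx(cap.area / 25.0, rel=0.01)
        assert h.max() * grid.dt >= 0.99 * integral  # one dominant bin

    def test_truncation_warning_reports_loss(self):
        mesh = rp.surface_mesh(rp.RingElement(3.0, 7.0), 0.2)
        short = rp.TimeGrid(0.0, 0.01, 100)  # ends before any arrival
        with pytest.warns(TruncationWarning):
            h = rp.spatial_impulse_response(mesh, (0, 0, 20.0), CS, short)
        assert np.all(h == 0.0)

    def test_source_on_surface_rejected(self, grid):
        mesh = rp.surface_mesh(rp.RingElement(3.0, 7.0), 0.2)
        with pytest.raises(ValueError):
            rp.spatial_impulse_response(mesh, mesh.points[0], CS, grid)


class TestElementSignal:
    def test_empty_source_list(self, grid, meas_array):
        s = rp.element_signal(meas_array.elements[0], [], CS, grid)
        assert np.all(s == 0.0)

    def test_superposition_exact(self, grid, meas_array):
        src = rp.SphereSource((0.0, 0.0, 25.0), 0.5)
        one = rp.element_signal(meas_array.elements[1], [src], CS, grid)
        two = rp.element_signal(meas_array.elements[1], [src, src], CS, grid)
        assert np.allclose(two, 2.0 * one)

    def test_arrival_time_matches_geometry(self, grid, meas_array):
        """0.5 mm source at 25 mm: the N-wave centre (midpoint between the
        signal extremes) sits at the mean-surface-point delay."""
        ring = meas_array.elements[1]  # fabricated ring2, 11-13 mm at 25 deg
        s = rp.element_signal(ring, [rp.SphereSource((0, 0, 25.0), 0.5)], CS, grid)
        rm = 0.5 * (ring.r_inner + ring.r_outer)
        zm = float(ring.elevation(rm))
        expected = np.hypot(rm, 25.0 - zm) / CS
        center_t = 0.5 * (grid.t[np.argmax(s)] + grid.t[np.argmin(s)])
        assert center_t == pytest.approx(expected, abs=2 * grid.dt)

    def test_mixed_diameters_convolved_per_source(self, grid, meas_array):
        el = meas_array.elements[0]
        a = rp.element_signal(el, [rp.SphereSource((0, 0, 20.0), 0.5)], CS, grid)
        b = rp.element_signal(el, [rp.SphereSource((0, 0, 30.0), 0.1)], CS, grid)
        ab = rp.element_signal(
            el,
            [
                rp.SphereSource((0, 0, 20.0), 0.5),
                rp.SphereSource((0, 0, 30.0), 0.1),
            ],
            CS,
            grid,
        )
        assert np.allclose(ab, a + b, atol=1e-12)

    def test_mesh_convergence_on_halving(self, grid, meas_array):
        """Halving the quadrature spacing changes s(t) by < 0.5% in L2."""
        sources = rp.sphere_column()
        for el in meas_array:
            s1 = rp.element_signal(rp.surface_mesh(el, 0.25), sources, CS, grid)
            s2 = rp.element_signal(rp.surface_mesh(el, 0.125), sources, CS, grid)
            rel = np.linalg.norm(s1 - s2) / np.linalg.norm(s2)
            assert rel < 5e-3, el.name

    def test_far_field_amplitude_decay(self, grid, meas_array):
        """Beyond a ring's focusing range the peak amplitude decays with depth."""
        ring = meas_array.elements[1]
        mesh = rp.surface_mesh(ring, 0.25)
        peaks = []
        for z in (32.0, 34.0, 36.0, 38.0):
            s = rp.element_signal(mesh, [rp.SphereSource((0, 0, z), 0.5)], CS, grid)
            peaks.append(np.abs(s).max())
        assert np.all(np.diff(peaks) < 0)


class TestSimulateBscan:
    def test_noise_free_runs_identical(self, grid, meas_array):
        src = rp.microsphere(25.0)
        a = rp.simulate_bscan(meas_array, src, [-1.0, 0.0, 1.0], CS, grid, seed=1)
        b = rp.simulate_bscan(meas_array, src, [-1.0, 0.0, 1.0], CS, grid, seed=99)
        assert np.array_equal(a.data, b.data)

    def test_seeded_noise_reproducible(self, grid, meas_array):
        src = rp.microsphere(25.0)
        a = rp.simulate_bscan(
            meas_array, src, [0.0], CS, grid, noise_rms=0.1, seed=5
        )
        b = rp.simulate_bscan(
            meas_array, src, [0.0], CS, grid, noise_rms=0.1, seed=5
        )
        c = rp.simulate_bscan(
            meas_array, src, [0.0], CS, grid, noise_rms=0.1, seed=6
        )
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_symmetric_phantom_gives_symmetric_bscan(self, grid, meas_array):
        sources = [
            rp.SphereSource((-1.5, 0.0, 24.0), 0.5),
            rp.SphereSource((1.5, 0.0, 24.0), 0.5),
        ]
        scan = np.arange(-2.0, 2.0 + 1e-9, 0.5)
        rf = rp.simulate_bscan(meas_array, sources, scan, CS, grid)
        assert np.allclose(rf.data, rf.data[:, ::-1, :], atol=1e-9)

    def test_scan_translation_reciprocity(self, grid, meas_array):
        """Scanning to +Δx equals rigidly shifting the sources by −Δx."""
        src = [rp.SphereSource((1.2, 0.4, 26.0), 0.5)]
        scanned = rp.simulate_bscan(meas_array, src, [0.7], CS, grid)
        shifted = rp.simulate_bscan(
            meas_array, [src[0].translated(dx=-0.7)], [0.0], CS, grid
        )
        assert np.array_equal(scanned.data, shifted.data)

    def test_monotone_scan_required(self, grid, meas_array):
        with pytest.raises(ValueError):
            rp.simulate_bscan(meas_array, rp.microsphere(25.0), [0.0, -1.0], CS, grid)


class TestEnvelope:
    def test_zero_input(self):
        assert np.all(rp.envelope(np.zeros(64)) == 0.0)

    def test_tone_burst_has_flat_envelope(self):
        t = np.arange(2048) * 0.01
        x = np.cos(2 * np.pi * 5.0 * t)
        env = rp.envelope(x)
        interior = env[200:-200]
        assert np.allclose(interior, 1.0, atol=1e-2)

    @given(st.integers(0, 2**31 - 1))
    def test_envelope_dominates_signal(self, seed):
        x = np.random.default_rng(seed).normal(size=256)
        env = rp.envelope(x)
        interior = slice(16, -16)
        assert np.all(env[interior] >= np.abs(x)[interior] - 1e-9)
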