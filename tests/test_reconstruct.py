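"""Dynamic-focusing reconstruction: model matrices, matched filtering,
coherence factor, preprocessing and sensitivity calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ringpam as rp
from ringpam.reconstruct import (
    CalibrationError,
    CalibrationTable,
    GridMismatchError,
    InvalidGridError,
    build_model_matrix,
    calibrate_sensitivity,
    coherence_factor,
    dynamic_focus_combine,
    preprocess_bscan,
    reconstruct_ascan,
    reconstruct_bscan,
    sensitivity_profile,
    tof_focus_bscan,
)

CS = 1.5


class TestModelMatrix:
    def test_rows_unit_norm(self, meas_matrices):
        for M in meas_matrices:
            norms = np.linalg.norm(M.rows, axis=1)
            assert np.allclose(norms, 1.0, atol=1e-12)

    def test_flat_ring_support_starts_at_inner_edge_arrival(self, meas_matrices, grid):
        """Row support for z = 25 mm starts at sqrt(25² + r_inner²)/cs."""
        M = meas_matrices[0]  # flat ring 4.0-7.25 mm
        k = int(np.argmin(np.abs(M.z - 25.0)))
        row = M.rows[k]
        t_geo = np.hypot(25.0, 4.0) / CS
        onset = grid.t[np.flatnonzero(np.abs(row) > 1e-3 * np.abs(row).max())[0]]
        # the probe N-wave (50 µm -> 33 ns) extends the support by half its width
        assert onset == pytest.approx(t_geo, abs=0.04)

    def test_peak_time_increasing_with_depth(self, meas_matrices, grid):
        for M in meas_matrices:
            peak_t = grid.t[np.argmax(np.abs(M.rows), axis=1)]
            assert np.all(np.diff(peak_t) > 0)

    def test_out_of_grid_depth_rejected(self, meas_array):
        short = rp.TimeGrid(4.0, 0.01, 500)  # ends at 9 µs
        with pytest.raises(InvalidGridError):
            build_model_matrix(meas_array.elements[0], np.array([25.0]), short, CS)

    def test_z_grid_validation(self, meas_array, grid):
        with pytest.raises(ValueError):
            build_model_matrix(meas_array.elements[0], np.array([25.0, 24.0]), grid, CS)


class TestReconstructAscan:
    def test_zero_signal_gives_zero_ascan(self, meas_matrices):
        a = reconstruct_ascan(meas_matrices[0], np.zeros(meas_matrices[0].grid.n_samples))
        assert np.all(a == 0.0)

    def test_matched_filter_self_consistency(self, meas_matrices):
        """Feeding row k back recovers its own depth (Cauchy–Schwarz)."""
        M = meas_matrices[1]
        for k in (50, 280, 500):
            a = reconstruct_ascan(M, M.rows[k])
            assert np.argmax(a) == k

    def test_linearity(self, meas_matrices, microsphere_rf_25):
        M = meas_matrices[0]
        s = microsphere_rf_25.data[0, 0]
        assert np.allclose(
            reconstruct_ascan(M, 2.5 * s), 2.5 * reconstruct_ascan(M, s)
        )

    def test_grid_mismatch_rejected(self, meas_matrices):
        with pytest.raises(GridMismatchError):
            reconstruct_ascan(meas_matrices[0], np.zeros(100))

    def test_end_to_end_localization(self, meas_array, meas_matrices, grid):
        """A 0.1 mm sphere at 25 mm localizes within one depth step."""
        rf = rp.simulate_bscan(meas_array, rp.microsphere(25.0), [0.0], CS, grid)
        for i, M in enumerate(meas_matrices):
            a = reconstruct_ascan(M, rf.data[i, 0])
            assert abs(M.z[np.argmax(np.abs(a))] - 25.0) <= 0.05 + 1e-9


class TestCoherenceFactor:
    def test_identical_ascans_fully_coherent(self):
        a = np.tile(np.sin(np.linspace(0, 6, 100)) + 2.0, (4, 1))
        assert np.allclose(coherence_factor(a), 1.0)

    def test_opposite_ascans_cancel(self):
        x = np.sin(np.linspace(0, 6, 100)) + 0.5
        cf = coherence_factor(np.stack([x, -x]))
        assert np.allclose(cf, 0.0)

    def test_half_coherent_pair(self):
        cf = coherence_factor(np.array([[1.0], [0.0]]))
        assert cf[0] == pytest.approx(0.5)

    def test_single_ring_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            cf = coherence_factor(np.ones((1, 10)))
        assert np.allclose(cf, 1.0)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    def test_bounded_between_zero_and_one(self, seed, n_rings):
        a = np.random.default_rng(seed).normal(size=(n_rings, 64))
        cf = coherence_factor(a)
        assert np.all(cf >= 0.0) and np.all(cf <= 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(4, 64))
        assert np.allclose(coherence_factor(a), coherence_factor(37.2 * a))


class TestDynamicFocusCombine:
    def test_single_nonzero_ring_divided_by_n(self):
        z = np.linspace(10, 40, 61)
        a = np.zeros((4, z.size))
        a[2] = 1.0
        combined, cf = dynamic_focus_combine(a, z)
        assert np.allclose(cf, 0.25)
        assert np.allclose(combined, 0.25)

    def test_constructive_sum_beats_single_ring(
        self, meas_array, meas_matrices, microsphere_rf_25
    ):
        ascans = np.stack(
            [
                reconstruct_ascan(M, microsphere_rf_25.data[i, 0])
                for i, M in enumerate(meas_matrices)
            ]
        )
        z = meas_matrices[0].z
        combined, cf = dynamic_focus_combine(ascans, z)
        k = int(np.argmin(np.abs(z - 25.0)))
        window = slice(k - 10, k + 10)
        single_best = np.abs(ascans[:, window]).max()
        assert (
            np.abs(combined[window]).max()
            >= single_best * cf[window][np.argmax(np.abs(combined[window]))] - 1e-12
        )

    def test_calibration_weights_applied(self):
        z = np.linspace(20, 30, 11)
        a = np.ones((2, z.size))
        table = CalibrationTable(depths=np.array([20.0, 30.0]), weights=np.array([2.0, 4.0]))
        combined, _ = dynamic_focus_combine(a, z, table)
        assert combined[0] == pytest.approx(2 * 2.0)
        assert combined[-1] == pytest.approx(2 * 4.0)

    def test_grid_mismatch(self):
        with pytest.raises(GridMismatchError):
            dynamic_focus_combine(np.ones((2, 5)), np.linspace(0, 1, 7))


class TestPreprocess:
    def test_scan_independent_artifact_removed(self, grid, meas_array):
        rf = rp.simulate_bscan(meas_array, rp.microsphere(25.0), [-1.0, 0.0, 1.0], CS, grid)
        artifact = np.sin(2 * np.pi * 3.0 * grid.t)
        dirty = rp.RFData(
            rf.data + artifact[None, None, :],
            rf.scan_x,
            grid,
            rf.element_names,
            dict(rf.meta),
        )
        clean = preprocess_bscan(dirty)
        expected = rf.data - rf.data.mean(axis=1, keepdims=True)
        assert np.allclose(clean.data, expected, atol=1e-12)

    def test_column_means_are_zero(self, grid, meas_array):
        rf = rp.simulate_bscan(meas_array, rp.microsphere(25.0), [-1.0, 0.0, 1.0], CS, grid)
        out = preprocess_bscan(rf)
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-14)

    def test_localized_peak_reduced_at_most_by_mean_share(self, grid, meas_array):
        rf = rp.simulate_bscan(
            meas_array, rp.microsphere(25.0), np.arange(-2.0, 2.1, 0.5), CS, grid
        )
        out = preprocess_bscan(rf)
        peak_before = np.abs(rf.data).max()
        peak_after = np.abs(out.data).max()
        assert peak_after >= peak_before * (1.0 - 1.0 / rf.n_scan) - 1e-12

    def test_single_position_passes_through_with_warning(self, microsphere_rf_25):
        with pytest.warns(UserWarning):
            out = preprocess_bscan(microsphere_rf_25)
        assert np.array_equal(out.data, microsphere_rf_25.data)


class TestCalibration:
    def test_reciprocal_weights(self):
        table = CalibrationTable.from_peaks([20.0, 25.0, 30.0], [2.0, 1.0, 0.5])
        assert np.allclose(table.weights, [0.5, 1.0, 2.0])

    def test_equal_peaks_give_equal_weights(self):
        table = CalibrationTable.from_peaks([20.0, 30.0], [3.0, 3.0])
        assert table.weights[0] == table.weights[1]

    def test_zero_peak_rejected_naming_depth(self):
        with pytest.raises(CalibrationError, match="27"):
            CalibrationTable.from_peaks([25.0, 27.0], [1.0, 0.0])

    def test_interpolation_clamped(self):
        table = CalibrationTable.from_peaks([20.0, 30.0], [1.0, 2.0])
        assert table.weight_at(10.0) == pytest.approx(1.0)
        assert table.weight_at(25.0) == pytest.approx(0.75)
        assert table.weight_at(40.0) == pytest.approx(0.5)

    def test_json_round_trip(self, tmp_path):
        table = CalibrationTable.from_peaks([20.0, 30.0], [1.0, 2.0])
        path = table.to_json(tmp_path / "calib.json")
        back = CalibrationTable.from_json(path)
        assert np.allclose(back.depths, table.depths)
        assert np.allclose(back.weights, table.weights)

    def test_self_calibration_closure(self, meas_array, meas_matrices, grid):
        """Applying the table to its own reference scans flattens the profile."""
        depths = [22.0, 27.0, 32.0]
        scans = [
            rp.simulate_bscan(meas_array, rp.microsphere(d), [0.0], CS, grid)
            for d in depths
        ]
        table = calibrate_sensitivity(scans, depths, meas_matrices)
        prof = sensitivity_profile(scans, depths, meas_matrices, table)
        assert np.allclose(prof, 1.0, rtol=1e-9)


class TestReconstructBscan:
    def test_zero_rf_gives_zero_image(self, meas_array, meas_matrices, grid):
        rf = rp.RFData(
            np.zeros((4, 3, grid.n_samples)),
            np.array([-1.0, 0.0, 1.0]),
            grid,
            meas_array.element_names,
        )
        img = reconstruct_bscan(rf, meas_matrices)
        assert np.all(img.image == 0.0)

    def test_image_nonnegative_and_cf_bounded(
        self, meas_array, meas_matrices, grid
    ):
        rf = rp.simulate_bscan(
            meas_array, rp.microsphere(25.0), [-0.5, 0.0, 0.5], CS, grid,
            noise_rms=1e-4, seed=3,
        )
        img = reconstruct_bscan(rf, meas_matrices)
        assert np.all(img.image >= 0.0)
        assert np.all((img.cf >= 0.0) & (img.cf <= 1.0))

    def test_scaling_rf_scales_image_cf_invariant(
        self, meas_array, meas_matrices, microsphere_rf_25
    ):
        rf2 = rp.RFData(
            3.0 * microsphere_rf_25.data,
            microsphere_rf_25.scan_x,
            microsphere_rf_25.grid,
            microsphere_rf_25.element_names,
            dict(microsphere_rf_25.meta),
        )
        a = reconstruct_bscan(microsphere_rf_25, meas_matrices)
        b = reconstruct_bscan(rf2, meas_matrices)
        assert np.allclose(b.image, 3.0 * a.image, rtol=1e-9)
        assert np.allclose(b.cf, a.cf, atol=1e-12)

    def test_positive_mode_discards_negative_lobes(
        self, meas_matrices, microsphere_rf_25
    ):
        env = reconstruct_bscan(microsphere_rf_25, meas_matrices, mode="envelope")
        pos = reconstruct_bscan(microsphere_rf_25, meas_matrices, mode="positive")
        assert np.all(pos.image >= 0.0)
        assert pos.image.max() <= env.image.max() * 1.05

    def test_element_count_mismatch(self, meas_matrices, microsphere_rf_25):
        with pytest.raises(GridMismatchError):
            reconstruct_bscan(microsphere_rf_25, meas_matrices[:2])

    def test_tof_mode_localizes_microsphere(self, meas_matrices, microsphere_rf_25):
        img = tof_focus_bscan(microsphere_rf_25, meas_matrices)
        assert abs(img.z[np.argmax(img.image[0])] - 25.0) <= 0.2
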