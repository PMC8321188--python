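import numpy as np
import pytest
from hypothesis import given, strategies as st

import mwbreast as mw
from mwbreast.errors import (
    DegenerateReferenceError,
    FormatError,
    IncompatibleRotationError,
)

from conftest import random_scan


class TestScanIO:
    def test_round_trip_is_bit_exact(self, toy_array, freqs5, tmp_path):
        scan = random_scan(toy_array, freqs5, seed=1)
        scan.meta["case_id"] = "toy"
        scan.meta["history"].append({"op": "calibrate"})
        path = tmp_path / "scan.h5"
        mw.write_scan(scan, path)
        back = mw.read_scan(path)
        assert np.array_equal(back.data, scan.data)
        assert np.array_equal(back.channels, scan.channels)
        assert np.array_equal(back.frequencies, scan.frequencies)
        assert np.allclose(back.array.positions, scan.array.positions)
        assert back.meta["case_id"] == "toy"
        assert back.meta["history"] == [{"op": "calibrate"}]

    def test_missing_field_names_it(self, toy_array, freqs5, tmp_path):
        import h5py

        path = tmp_path / "scan.h5"
        mw.write_scan(random_scan(toy_array, freqs5, seed=2), path)
        with h5py.File(path, "a") as f:
            del f["freqs"]
        with pytest.raises(FormatError, match="freqs"):
            mw.read_scan(path)


class TestCalibration:
    def test_unit_gain_reference_gives_unit_factors(self, ring10_array, freqs5):
        ref = mw.simulate_reference_scan(ring10_array, freqs5, mw.SimulationConfig())
        factors = mw.compute_calibration(ref)
        assert np.allclose(factors.factors, 1.0, atol=1e-9)

    def test_single_ring_recovers_inverse_gains(self, ring10_array, freqs5):
        rng = np.random.default_rng(3)
        gains = mw.draw_gains(10, rng)
        ref = mw.simulate_reference_scan(
            ring10_array, freqs5, mw.SimulationConfig(antenna_gains=gains)
        )
        f = mw.compute_calibration(ref).factors
        # proportional to 1/|g| up to one global scale
        product = f * np.abs(gains)
        assert np.ptp(product) / product.mean() < 1e-8

    def test_postcalibration_symmetric_channels_equal(self, array24, freqs21):
        """End-to-end gain cancellation on the three-ring array."""
        rng = np.random.default_rng(11)
        gains = mw.draw_gains(24, rng)
        ref = mw.simulate_reference_scan(
            array24, freqs21, mw.SimulationConfig(antenna_gains=gains)
        )
        cal = mw.apply_calibration(ref, mw.compute_calibration(ref))
        mags = np.abs(cal.data).mean(axis=1)
        perm = array24.rotation_permutation(array24.azimuthal_step)
        for row in range(cal.n_channels):
            tx, rx = cal.channels[row]
            mapped = cal.channel_row(int(perm[tx]), int(perm[rx]))
            assert mags[row] == pytest.approx(mags[mapped], rel=1e-6)

    def test_zero_reference_is_degenerate(self, toy_array, freqs5):
        ref = mw.simulate_reference_scan(
            toy_array, freqs5, mw.SimulationConfig(), skin_residual_scale=0.0
        )
        with pytest.raises(DegenerateReferenceError):
            mw.compute_calibration(ref)

    def test_apply_identity_and_bilinearity(self, toy_array, freqs5):
        scan = random_scan(toy_array, freqs5, seed=4)
        ones = mw.CalibrationFactors(np.ones(6))
        assert np.array_equal(mw.apply_calibration(scan, ones).data, scan.data)
        twos = mw.CalibrationFactors(np.full(6, 2.0))
        assert np.allclose(mw.apply_calibration(scan, twos).data, 4.0 * scan.data)

    def test_apply_then_inverse_restores(self, toy_array, freqs5):
        scan = random_scan(toy_array, freqs5, seed=5)
        f = np.linspace(0.5, 2.0, 6)
        out = mw.apply_calibration(
            mw.apply_calibration(scan, mw.CalibrationFactors(f)),
            mw.CalibrationFactors(1.0 / f),
        )
        assert np.allclose(out.data, scan.data, atol=1e-12 * np.abs(scan.data).max())

    def test_factor_count_mismatch(self, toy_array, freqs5):
        scan = random_scan(toy_array, freqs5, seed=6)
        with pytest.raises(Exception):
            mw.apply_calibration(scan, mw.CalibrationFactors(np.ones(5)))

    def test_history_appended(self, toy_array, freqs5):
        scan = random_scan(toy_array, freqs5, seed=7)
        out = mw.apply_calibration(scan, mw.CalibrationFactors(np.ones(6)))
        assert out.meta["history"][-1]["op"] == "calibrate"
        assert scan.meta["history"] == []  # original untouched


def _rotate_channels(scan, k):
    """Scan whose data is the original rotated by k azimuthal steps."""
    perm = scan.array.rotation_permutation(k * scan.array.azimuthal_step)
    lut = {(int(t), int(r)): i for i, (t, r) in enumerate(scan.channels)}
    rows = [lut[(int(perm[t]), int(perm[r]))] for t, r in scan.channels]
    return scan.with_data(scan.data[rows])


class TestRotationalSubtraction:
    def test_constructed_symmetric_scan_cancels_exactly(self, toy_array, freqs5):
        """A scan built to be exactly orbit-invariant maps to exact zero."""
        scan = random_scan(toy_array, freqs5, seed=8)
        perm = toy_array.rotation_permutation(toy_array.azimuthal_step)
        # symmetrize: average data over the rotation orbit, copying bitwise
        data = scan.data.copy()
        lut = {(int(t), int(r)): i for i, (t, r) in enumerate(scan.channels)}
        for i, (t, r) in enumerate(scan.channels):
            orbit_rep = min(
                lut[key]
                for key in _orbit_keys(perm, int(t), int(r), toy_array)
            )
            data[i] = scan.data[orbit_rep]
        sym = scan.with_data(data)
        out = mw.rotational_subtract(sym, toy_array.azimuthal_step)
        assert np.all(out.data == 0)

    def test_simulated_centered_scatterer_cancels(self, toy_array, freqs5):
        ph = mw.BreastPhantom(
            vgf_class=0,
            scatterers=(),
            tumor=mw.Scatterer(np.array([0.0, 0.0, 0.03]), 0.005, 70.0, 6.0, "tumor"),
        )
        scan = mw.simulate_scan(ph, toy_array, freqs5, mw.SimulationConfig())
        out = mw.rotational_subtract(scan, toy_array.azimuthal_step)
        assert np.max(np.abs(out.data)) < 1e-9 * np.max(np.abs(scan.data))

    def test_zero_angle_is_self_subtraction(self, toy_array, freqs5):
        scan = random_scan(toy_array, freqs5, seed=9)
        out = mw.rotational_subtract(scan, 0.0)
        assert np.all(out.data == 0)

    def test_off_center_scatterer_survives_and_not_idempotent(self, toy_array, freqs5):
        ph = mw.BreastPhantom(
            vgf_class=0,
            scatterers=(),
            tumor=mw.Scatterer(np.array([0.02, 0.01, 0.03]), 0.005, 70.0, 6.0, "tumor"),
        )
        scan = mw.simulate_scan(ph, toy_array, freqs5, mw.SimulationConfig())
        once = mw.rotational_subtract(scan, toy_array.azimuthal_step)
        assert np.max(np.abs(once.data)) > 0
        twice = mw.rotational_subtract(once, toy_array.azimuthal_step)
        assert not np.allclose(once.data, twice.data)

    def test_incompatible_angle_raises(self, toy_array, freqs5):
        scan = random_scan(toy_array, freqs5, seed=10)
        with pytest.raises(IncompatibleRotationError):
            mw.rotational_subtract(scan, 37.0)

    @given(st.integers(0, 2**31 - 1), st.integers(0, 2**31 - 1))
    def test_linearity(self, seed_a, seed_b):
        array = mw.build_array(4, 0.07, ((70.0, 4),))
        freqs = mw.FrequencyGrid.default(3)
        a = random_scan(array, freqs, seed=seed_a)
        b = random_scan(array, freqs, seed=seed_b)
        both = a.with_data(a.data + 2.0 * b.data)
        out = mw.rotational_subtract(both, array.azimuthal_step)
        ra = mw.rotational_subtract(a, array.azimuthal_step)
        rb = mw.rotational_subtract(b, array.azimuthal_step)
        assert np.allclose(out.data, ra.data + 2.0 * rb.data, rtol=1e-12)

    def test_orbit_sum_telescopes_to_zero(self, toy_array, freqs5):
        """Summing s o pi^k - s o pi^(k+1) over the whole orbit cancels."""
        scan = random_scan(toy_array, freqs5, seed=12)
        total = np.zeros_like(scan.data)
        for k in range(toy_array.rotational_symmetry_order):
            rotated = _rotate_channels(scan, k)
            total += mw.rotational_subtract(rotated, toy_array.azimuthal_step).data
        assert np.allclose(total, 0.0, atol=1e-12 * np.abs(scan.data).max())

    def test_commutes_with_uniform_calibration(self, toy_array, freqs5):
        scan = random_scan(toy_array, freqs5, seed=13)
        f = mw.CalibrationFactors(np.full(6, 1.7))
        a = mw.rotational_subtract(
            mw.apply_calibration(scan, f), toy_array.azimuthal_step
        )
        b = mw.apply_calibration(
            mw.rotational_subtract(scan, toy_array.azimuthal_step), f
        )
        assert np.allclose(a.data, b.data, rtol=1e-12)


def _orbit_keys(perm, t, r, array):
    keys = []
    for _ in range(array.rotational_symmetry_order):
        keys.append((t, r))
        t, r = int(perm[t]), int(perm[r])
    return keys
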