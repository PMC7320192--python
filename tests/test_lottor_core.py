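"""Restoration core: mask calibration, constraint operators, iteration."""

import numpy as np
import pytest

from lottor._fourier import cfftn
from lottor.io_maps import DensityMap
from lottor.lottor_core import (LottorParams, Mask, apply_real_constraints,
                                make_mask, replace_data_zone, run_lottor,
                                run_round)
from lottor.tomo_sim import DataZone, make_data_zone

V_PER_DA = 1.21


def _params(**overrides):
    defaults = dict(tilt_max=30.0, mw_da=5000.0, voxel_size=1.0,
                    mask_filter_res=10.0, volume_factor=3.0,
                    n_iter_per_round=10, n_rounds=1)
    defaults.update(overrides)
    return LottorParams(**defaults)


def _ball_map(n=32, radius=8.0, soft=2.0):
    c = n // 2
    x, y, z = np.meshgrid(*(np.arange(n, dtype=float) - c,) * 3, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    return DensityMap(1.0 / (1.0 + np.exp((r - radius) / soft)), 1.0)


# ---------------------------------------------------------------------------
# scalar reference implementations (independent of the package's FFT path)

def _dft3_scalar(values, sign=-1):
    """Centered 3D DFT by explicit loops; DC at n//2 on each axis."""
    n = values.shape[0]
    c = n // 2
    out = np.zeros((n, n, n), dtype=complex)
    for ka in range(n):
        for kb in range(n):
            for kc in range(n):
                acc = 0.0 + 0.0j
                for va in range(n):
                    for vb in range(n):
                        for vc in range(n):
                            phase = ((ka - c) * (va - c) + (kb - c) * (vb - c)
                                     + (kc - c) * (vc - c)) / n
                            acc += values[va, vb, vc] * np.exp(
                                sign * 2j * np.pi * phase)
                out[ka, kb, kc] = acc
    if sign == +1:
        out /= n**3
    return out


def _iteration_scalar(start, f0, mask, zone):
    """One constraint cycle, all scalar: Eq-style per-voxel conditionals."""
    n = start.shape[0]
    constrained = np.zeros((n, n, n))
    for v in np.ndindex(n, n, n):
        if mask[v] and start[v].real >= 0:
            constrained[v] = start[v].real
    spectrum = _dft3_scalar(constrained, sign=-1)
    for v in np.ndindex(n, n, n):
        if zone[v]:
            spectrum[v] = f0[v]
    return _dft3_scalar(spectrum, sign=+1)


class TestMakeMask:
    def test_volume_calibration(self):
        density = _ball_map()
        params = _params(mw_da=4000.0, volume_factor=3.0)
        mask = make_mask(density, params)
        target = 3.0 * 4000.0 * V_PER_DA
        assert mask.n_voxels == pytest.approx(target, rel=0.02)

    def test_volume_factor_ratio(self):
        density = _ball_map()
        large = make_mask(density, _params(mw_da=2000.0, volume_factor=3.8))
        tight = make_mask(density, _params(mw_da=2000.0, volume_factor=1.75))
        assert tight.n_voxels / large.n_voxels == pytest.approx(1.75 / 3.8,
                                                                rel=0.03)

    def test_spherical_map_gives_spherical_mask(self):
        density = _ball_map()
        mask = make_mask(density, _params(mw_da=3000.0))
        m = mask.membership
        # symmetric under each axis reflection about the center voxel
        for axis in range(3):
            flipped = np.flip(m, axis=axis)
            flipped = np.roll(flipped, 1, axis=axis)
            assert (m ^ flipped).mean() < 0.02

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            make_mask(_ball_map(), _params(mw_da=1e7, volume_factor=4.0))

    def test_zero_map_rejected(self):
        zero = DensityMap(np.zeros((16, 16, 16)), 1.0)
        with pytest.raises(ValueError):
            make_mask(zero, _params())


class TestRealConstraints:
    def test_matches_scalar_loop_on_complex_input(self):
        rng = np.random.default_rng(9)
        n = 4
        values = rng.normal(size=(n, n, n)) + 1j * rng.normal(size=(n, n, n))
        membership = rng.random((n, n, n)) > 0.4
        membership[0, 0, 0] = True
        membership[1, 1, 1] = False
        mask = Mask(membership, 10.0, 3.0, 0.0)
        expected = np.zeros((n, n, n))
        for v in np.ndindex(n, n, n):
            if membership[v] and values[v].real >= 0:
                expected[v] = values[v].real
        out = apply_real_constraints(values, mask)
        np.testing.assert_array_equal(out, expected)

    def test_all_negative_inside_clamps_to_zero(self):
        membership = np.zeros((4, 4, 4), dtype=bool)
        membership[1:3, 1:3, 1:3] = True
        mask = Mask(membership, 10.0, 3.0, 0.0)
        out = apply_real_constraints(-np.ones((4, 4, 4)), mask)
        assert np.all(out == 0)

    def test_positive_map_only_masked(self):
        membership = np.zeros((4, 4, 4), dtype=bool)
        membership[:2] = True
        mask = Mask(membership, 10.0, 3.0, 0.0)
        values = np.full((4, 4, 4), 2.5)
        out = apply_real_constraints(values, mask)
        assert np.all(out[:2] == 2.5)
        assert np.all(out[2:] == 0.0)

    def test_grid_mismatch_rejected(self):
        mask = Mask(np.ones((4, 4, 4), dtype=bool) ^ np.eye(4, dtype=bool)[..., None],
                    10.0, 3.0, 0.0)
        with pytest.raises(ValueError, match="mismatch"):
            apply_real_constraints(np.zeros((5, 5, 5)), mask)


class TestReplaceDataZone:
    def test_matches_per_voxel_conditional(self):
        rng = np.random.default_rng(10)
        n = 8
        current = rng.normal(size=(n, n, n)) + 1j * rng.normal(size=(n, n, n))
        original = rng.normal(size=(n, n, n)) + 1j * rng.normal(size=(n, n, n))
        zone = make_data_zone(n, 45.0)
        out = replace_data_zone(current, original, zone)
        for v in np.ndindex(n, n, n):
            expected = original[v] if zone.membership[v] else current[v]
            assert out[v] == expected

    def test_full_zone_returns_original(self):
        rng = np.random.default_rng(11)
        n = 8
        current = rng.normal(size=(n, n, n)).astype(complex)
        original = rng.normal(size=(n, n, n)).astype(complex)
        zone = make_data_zone(n, 90.0)
        np.testing.assert_array_equal(
            replace_data_zone(current, original, zone), original)

    def test_empty_zone_returns_current(self):
        rng = np.random.default_rng(12)
        n = 8
        current = rng.normal(size=(n, n, n)).astype(complex)
        original = rng.normal(size=(n, n, n)).astype(complex)
        zone = DataZone(np.zeros((n, n, n), dtype=bool), 0.0)
        np.testing.assert_array_equal(
            replace_data_zone(current, original, zone), current)


class TestRunRound:
    def _fixture(self, n=32):
        density = _ball_map(n)
        params = _params(mw_da=3000.0)
        mask = make_mask(density, params)
        return density, mask

    def test_full_zone_fixed_point(self):
        density, mask = self._fixture()
        zone = make_data_zone(32, 90.0)
        one, _ = run_round(density, mask, zone, 1)
        many, _ = run_round(density, mask, zone, 5)
        expected = apply_real_constraints(density.values, mask)
        np.testing.assert_allclose(one.values, expected, atol=1e-10)
        np.testing.assert_allclose(many.values, expected, atol=1e-10)

    def test_zero_iterations_identity(self):
        density, mask = self._fixture()
        zone = make_data_zone(32, 30.0)
        out, trace = run_round(density, mask, zone, 0)
        np.testing.assert_array_equal(out.values, density.values)
        assert trace.size == 0

    def test_single_iteration_matches_scalar_oracle(self):
        """One full constraint cycle on a 4³ grid vs an explicit-loop DFT."""
        rng = np.random.default_rng(13)
        n = 4
        values = rng.normal(size=(n, n, n)) + 1.0
        density = DensityMap(values, 1.0)
        membership = rng.random((n, n, n)) > 0.3
        membership[0, 0, 0] = False
        membership[2, 2, 2] = True
        mask = Mask(membership, 10.0, 3.0, 0.0)
        zone = make_data_zone(n, 45.0)

        out, _ = run_round(density, mask, zone, 1)

        f0 = _dft3_scalar(values, sign=-1)
        after_cycle = _iteration_scalar(values.astype(complex), f0,
                                        membership, zone.membership)
        expected = np.zeros((n, n, n))
        for v in np.ndindex(n, n, n):
            if membership[v] and after_cycle[v].real >= 0:
                expected[v] = after_cycle[v].real
        np.testing.assert_allclose(out.values, expected, atol=1e-10)

    def test_wedge_energy_grows_and_iteration_settles(self):
        density = _ball_map(32, radius=7.0, soft=1.0)
        params = _params(mw_da=2500.0)
        mask = make_mask(density, params)
        zone = make_data_zone(32, 30.0)
        f_init = cfftn(apply_real_constraints(density.values, mask))
        wedge = ~zone.membership

        out, trace = run_round(density, mask, zone, 100)
        f_out = cfftn(out.values)
        energy_before = np.sum(np.abs(f_init[wedge]) ** 2)
        energy_after = np.sum(np.abs(f_out[wedge]) ** 2)
        assert energy_after > energy_before
        assert trace[-1] < trace[0]

    def test_output_satisfies_constraints_exactly(self):
        density, mask = self._fixture()
        zone = make_data_zone(32, 30.0)
        out, _ = run_round(density, mask, zone, 20)
        assert np.isrealobj(out.values)
        assert np.all(out.values[~mask.membership] == 0.0)
        assert np.all(out.values[mask.membership] >= 0.0)

    def test_data_zone_fidelity_after_convergence(self, smooth_phantom48):
        """On a consistent noise-free fixture (a wedge-limited reconstruction
        of a particle the mask contains) the final constraint application
        perturbs the locked data by well under 5%."""
        from lottor.tomo_sim import backproject, project_tilt_series, tilt_range

        from lottor.phantom import equivalent_mass_da

        initial = backproject(project_tilt_series(smooth_phantom48,
                                                  tilt_range(30.0)))
        params = _params(mw_da=equivalent_mass_da(smooth_phantom48),
                         volume_factor=3.0, mask_filter_res=10.0)
        mask = make_mask(initial, params)
        zone = make_data_zone(48, 30.0)
        out, _ = run_round(initial, mask, zone, 200)
        f0 = cfftn(initial.values)
        f_out = cfftn(out.values)
        z = zone.membership
        rel = (np.linalg.norm(f_out[z] - f0[z]) / np.linalg.norm(f0[z]))
        assert rel < 0.05

    def test_hermitian_symmetry_preserved(self):
        density, mask = self._fixture()
        zone = make_data_zone(32, 30.0)
        out, _ = run_round(density, mask, zone, 10)
        spectrum = cfftn(out.values)
        flipped = np.conj(np.roll(spectrum[::-1, ::-1, ::-1], 1, axis=(0, 1, 2)))
        np.testing.assert_allclose(spectrum, flipped, atol=1e-6 * np.abs(
            spectrum).max())


class TestRunLottor:
    def test_single_round_equals_run_round(self):
        density = _ball_map()
        params = _params(mw_da=3000.0, n_iter_per_round=15, n_rounds=1)
        zone = make_data_zone(32, params.tilt_max)
        mask = make_mask(density, params)
        direct, _ = run_round(density, mask, zone, 15)
        result = run_lottor(density, params)
        np.testing.assert_allclose(result.final_map.values, direct.values,
                                   atol=1e-12)
        assert len(result.per_round_maps) == 1

    def test_round_count_and_traces(self):
        density = _ball_map()
        params = _params(mw_da=3000.0, n_iter_per_round=5, n_rounds=3)
        result = run_lottor(density, params)
        assert len(result.per_round_maps) == 3
        assert len(result.convergence) == 3
        assert all(np.all(t >= 0) for t in result.convergence)

    def test_all_zero_map_rejected(self):
        zero = DensityMap(np.zeros((16, 16, 16)), 1.0)
        with pytest.raises(ValueError, match="zero"):
            run_lottor(zero, _params())

    def test_mask_override_used(self):
        density = _ball_map()
        membership = np.zeros((32, 32, 32), dtype=bool)
        membership[10:22, 10:22, 10:22] = True
        override = Mask(membership, 10.0, 3.0, 0.0, source="external")
        params = _params(mw_da=3000.0, n_iter_per_round=3)
        params.mask_override = override
        result = run_lottor(density, params)
        assert np.all(result.final_map.values[~membership] == 0.0)
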