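"""Scenario sets, radiological depth, pencil-beam kernels, dose influence."""

import numpy as np
import pytest
from scipy.integrate import quad

from mbrtplan.beams import (
    Field,
    ScenarioSet,
    build_dose_influence,
    field_dose_matrix,
    lateral_profile,
    make_scenario_set,
    nominal_only,
    pdd_electron,
    pdd_photon,
    photon_beamlet_dose,
    electron_beamlet_dose,
    practical_range_mm,
    radiological_depth,
    sample_voxels,
    SAD_MM,
)
from mbrtplan.geometry import Structure, VoxelGrid

from conftest import sphere_structure, water_grid


class TestScenarioSet:
    def test_three_axes_gives_seven_equal_scenarios(self):
        ss = make_scenario_set(5.0, ("LR", "AP", "SI"))
        assert len(ss) == 7
        assert np.allclose(ss.importance, 1.0 / 7.0)
        # +-5 mm along each axis, nominal first
        assert np.array_equal(ss.shifts_mm[0], [0, 0, 0])
        mags = np.abs(ss.shifts_mm[1:]).sum(axis=1)
        assert np.all(mags == 5.0)

    def test_empty_axes_is_nominal_only(self):
        ss = make_scenario_set(5.0, ())
        assert len(ss) == 1 and ss.importance[0] == 1.0

    def test_single_axis_si_shifts_z(self):
        ss = make_scenario_set(5.0, ("SI",))
        assert len(ss) == 3
        assert np.array_equal(ss.shifts_mm[:, 2], [0.0, 5.0, -5.0])
        assert np.all(ss.shifts_mm[:, :2] == 0.0)

    def test_duplicate_nominal_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSet(np.zeros((2, 3)), np.array([0.5, 0.5]))


class TestRadiologicalDepth:
    def test_homogeneous_water_equals_geometric_depth(self, small_water_grid):
        g = small_water_grid
        entry = np.array([0.0, -48.0, 0.0])
        d = radiological_depth(g, entry, (0.0, 1.0, 0.0), entry + [0, 50.0, 0])
        assert d == pytest.approx(50.0, abs=2.0)

    def test_half_density_slab(self):
        grid = water_grid(n=30, spacing=2.0)
        vals = grid.values.copy()
        ys = grid.voxel_centers()[1]
        vals[:, ys < -10.0, :] = 0.5  # first 20 mm of the path at density 0.5
        grid.values = vals
        entry = np.array([0.0, -30.0, 0.0])
        d = radiological_depth(grid, entry, (0.0, 1.0, 0.0), entry + [0, 50.0, 0])
        assert d == pytest.approx(40.0, abs=1.5)

    def test_point_at_entry_is_zero(self, small_water_grid):
        entry = np.array([0.0, -48.0, 0.0])
        assert radiological_depth(small_water_grid, entry, (0, 1.0, 0), entry) == 0.0

    def test_point_behind_entry_raises(self, small_water_grid):
        entry = np.array([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="behind"):
            radiological_depth(small_water_grid, entry, (0, 1.0, 0), entry - [0, 10, 0])


def _on_axis_points(depths, surface_y=-48.0):
    return np.array([[0.0, surface_y + d, 0.0] for d in depths])


class TestPhotonKernel:
    def test_attenuation_beyond_buildup(self, small_water_grid):
        f = Field("p", "photon", 6.0, 0.0, n_rows=4, n_cols=4)
        pts = _on_axis_points([20.0, 80.0])
        m = field_dose_matrix(f, small_water_grid, (0, 0, 0), pts)
        central = m.sum(axis=1)  # all beamlets: removes penumbra sensitivity
        assert central[1] < central[0]

    def test_dose_positive_at_depth(self):
        grid = water_grid(n=36, spacing=8.0)  # 288 mm cube
        f = Field("p", "photon", 6.0, 0.0, n_rows=4, n_cols=4)
        pts = _on_axis_points([260.0], surface_y=-144.0 + 4.0)
        m = field_dose_matrix(f, grid, (0, 0, 0), pts)
        assert m.sum() > 0.0

    def test_zero_shift_bitexact_nominal(self, small_water_grid):
        f = Field("p", "photon", 6.0, 0.0, n_rows=4, n_cols=4)
        d0 = photon_beamlet_dose(f, 5, small_water_grid)
        ds = photon_beamlet_dose(f, 5, small_water_grid, shift_mm=(0.0, 0.0, 0.0))
        assert np.array_equal(d0, ds)

    def test_wrong_modality_rejected(self, small_water_grid):
        f = Field("e", "electron", 12.0, 0.0, n_rows=4, n_cols=4)
        with pytest.raises(ValueError):
            photon_beamlet_dose(f, 0, small_water_grid)

    def test_inverse_square_in_low_attenuation_medium(self):
        # water slab completes buildup, then near-vacuum: the remaining
        # falloff is the inverse-square distance factor
        grid = water_grid(n=60, spacing=5.0)
        vals = np.full(grid.shape, 0.001)
        ys = grid.voxel_centers()[1]
        vals[:, ys < -120.0, :] = 1.0  # ~30 mm water at the entrance
        grid.values = vals
        f = Field("p", "photon", 6.0, 0.0, n_rows=2, n_cols=2)
        d1, d2 = 60.0, 160.0  # depths beyond isocenter-coordinates origin
        pts = np.array([[0.0, d1, 0.0], [0.0, d2, 0.0]])
        m = field_dose_matrix(f, grid, (0, 0, 0), pts).sum(axis=1)
        expected = ((SAD_MM + d2) / (SAD_MM + d1)) ** 2
        assert m[0] / m[1] == pytest.approx(expected, rel=0.02)


class TestElectronKernel:
    def test_22mev_tail_only_beyond_range(self):
        assert practical_range_mm(22.0) == 110.0
        tail = pdd_electron(np.array([115.0, 150.0, 250.0]), 22.0)
        peak = pdd_electron(np.array([10.0]), 22.0)[0]
        assert np.all(tail <= 0.02 * peak)
        assert np.all(tail > 0.0)  # bremsstrahlung persists

    def test_6mev_fall_off_by_30mm(self):
        assert practical_range_mm(6.0) == 30.0
        assert pdd_electron(np.array([30.0]), 6.0)[0] == 0.0
        assert pdd_electron(np.array([35.0]), 6.0)[0] == 0.0  # no tail below 15 MeV
        assert pdd_electron(np.array([20.0]), 6.0)[0] > 0.5

    def test_kernel_lateral_normalization(self):
        # integral of the finite-beamlet profile equals the beamlet width
        for sigma in (2.0, 5.0, 12.0):
            integral, _ = quad(lambda x: lateral_profile(x, sigma), -80, 80)
            assert integral == pytest.approx(5.0, rel=0.01)

    def test_beyond_range_tail_bounded(self, small_water_grid):
        f = Field("e", "electron", 15.0, 0.0, n_rows=2, n_cols=2, ssd_mm=723.0)
        pts = _on_axis_points([10.0, 85.0])  # R_p(15) = 75 mm; 85 > R_p + 5
        m = field_dose_matrix(f, small_water_grid, (0, 0, 0), pts)
        assert m[1].max() <= 0.025 * m[0].max()

    def test_wrong_modality_rejected(self, small_water_grid):
        f = Field("p", "photon", 6.0, 0.0, n_rows=4, n_cols=4)
        with pytest.raises(ValueError):
            electron_beamlet_dose(f, 0, small_water_grid)

    def test_invalid_electron_energy_rejected(self):
        with pytest.raises(ValueError, match="electron energy"):
            Field("e", "electron", 10.0, 0.0)


class TestDoseInfluence:
    def test_single_field_nominal_only(self, tiny_case):
        grid, structures = tiny_case
        f = Field("p", "photon", 6.0, 0.0, n_rows=6, n_cols=6)
        infl = build_dose_influence([f], grid, structures, nominal_only())
        assert len(infl.matrices) == 1 and len(infl.matrices[0]) == 1
        m = infl.matrix(0, 0)
        assert m.shape == (infl.voxels.n, 36)
        assert (m.data >= 0).all()

    def test_seven_scenarios_nominal_matches_zero_shift(self, tiny_case):
        grid, structures = tiny_case
        f = Field("p", "photon", 6.0, 0.0, n_rows=6, n_cols=6)
        ss = make_scenario_set(5.0)
        infl = build_dose_influence([f], grid, structures, ss)
        assert len(infl.matrices[0]) == 7
        nominal = infl.matrix(0, 0)
        explicit = build_dose_influence([f], grid, structures, nominal_only()).matrix(0, 0)
        assert np.array_equal(nominal.toarray(), explicit.toarray())

    def test_shift_consistency_translation(self, tiny_case):
        # homogeneous body: scenario dose = nominal dose translated by -s,
        # i.e. D_s(r) = D_0(r + s), within 2% of the beamlet max
        grid, structures = tiny_case
        f = Field("p", "photon", 6.0, 30.0, n_rows=6, n_cols=6)
        shift = np.array([5.0, 0.0, 0.0])
        vox = sample_voxels(grid, structures)
        interior = np.all(
            (vox.positions_mm + shift >= np.asarray(grid.origin_mm) + 5)
            & (vox.positions_mm + shift <= -np.asarray(grid.origin_mm) - 5),
            axis=1,
        )
        pts = vox.positions_mm[interior]
        d_s = field_dose_matrix(f, grid, shift, pts)
        d_0_translated = field_dose_matrix(f, grid, (0, 0, 0), pts + shift)
        peak = d_0_translated.max(axis=0)
        err = np.abs(d_s - d_0_translated).max(axis=0)
        assert np.all(err <= 0.02 * np.maximum(peak, peak.max() * 0.1))

    def test_no_structure_voxels_raises(self, small_water_grid):
        f = Field("p", "photon", 6.0, 0.0, n_rows=4, n_cols=4)
        empty = Structure("ctv", np.zeros(small_water_grid.shape, bool), "target")
        with pytest.raises(ValueError, match="no structure voxels"):
            build_dose_influence([f], small_water_grid, [empty], nominal_only())
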