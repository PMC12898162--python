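import numpy as np
import pytest

from ionopore.grids import (
    GridSpec,
    ScalarGrid3D,
    assign_charges,
    axial_charge_profile,
    axial_mass_density_profile,
    time_average,
    time_averaged_charge_density,
)
from ionopore.model import Trajectory

from conftest import make_frame


class TestGridSpec:
    def test_from_box_recovers_box_exactly(self):
        spec = GridSpec.from_box((18.1, 18.1, 12.6), 0.1)
        assert spec.matches_box((18.1, 18.1, 12.6))
        assert all(n % 2 == 0 for n in spec.dims)
        assert all(abs(s - 0.1) < 0.01 for s in spec.spacing)

    def test_axis_centers(self):
        spec = GridSpec((0.5, 0.5, 0.5), (4, 4, 8))
        np.testing.assert_allclose(spec.axis_centers(2), 0.5 * np.arange(8))

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError):
            GridSpec((0.1, 0.1, 0.1), (2, 4, 4))


class TestChargeAssignment:
    def test_ngp_puts_whole_charge_on_nearest_node(self):
        frame, _ = make_frame([[1.02, 2.01, 2.99]], ["NA"], box=(6.0, 6.0, 12.0))
        spec = GridSpec.from_box((6.0, 6.0, 12.0), 1.0)
        grid = assign_charges(frame, spec, np.array([1.0]), scheme="NGP")
        assert grid.values[1, 2, 3] == pytest.approx(1.0 / spec.voxel_volume)
        assert grid.total == pytest.approx(1.0)

    def test_cic_on_node_is_pointlike(self):
        frame, _ = make_frame([[1.0, 2.0, 3.0]], ["NA"], box=(6.0, 6.0, 12.0))
        spec = GridSpec.from_box((6.0, 6.0, 12.0), 1.0)
        grid = assign_charges(frame, spec, np.array([1.0]), scheme="CIC")
        assert grid.values[1, 2, 3] == pytest.approx(1.0 / spec.voxel_volume)

    def test_cic_midpoint_splits_evenly(self):
        frame, _ = make_frame([[1.5, 2.0, 3.0]], ["NA"], box=(6.0, 6.0, 12.0))
        spec = GridSpec.from_box((6.0, 6.0, 12.0), 1.0)
        grid = assign_charges(frame, spec, np.array([1.0]), scheme="CIC")
        assert grid.values[1, 2, 3] == pytest.approx(0.5 / spec.voxel_volume)
        assert grid.values[2, 2, 3] == pytest.approx(0.5 / spec.voxel_volume)

    def test_periodic_wrap_near_box_edge(self):
        frame, _ = make_frame([[5.9, 0.0, 0.0]], ["NA"], box=(6.0, 6.0, 12.0))
        spec = GridSpec.from_box((6.0, 6.0, 12.0), 1.0)
        grid = assign_charges(frame, spec, np.array([1.0]), scheme="CIC")
        assert grid.total == pytest.approx(1.0)
        assert grid.values[0, 0, 0] > 0  # wrapped share lands on node 0

    def test_charge_conservation_both_schemes(self, rng):
        box = (6.0, 6.0, 12.0)
        pos = rng.uniform(0, 1, size=(200, 3)) * np.asarray(box)
        names = ["NA"] * 100 + ["CL"] * 100
        frame, _ = make_frame(pos, names, box=box)
        charges = np.array([1.0] * 100 + [-1.0] * 100)
        spec = GridSpec.from_box(box, 0.3)
        for scheme in ("NGP", "CIC"):
            grid = assign_charges(frame, spec, charges, scheme=scheme)
            assert abs(grid.total - charges.sum()) < 1e-12

    def test_ion_mask_excludes_water(self):
        frame, _ = make_frame(
            [[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]], ["NA", "W"], box=(6.0, 6.0, 12.0)
        )
        spec = GridSpec.from_box((6.0, 6.0, 12.0), 1.0)
        grid = assign_charges(
            frame, spec, np.array([1.0, 5.0]), ion_mask=np.array([True, False])
        )
        assert grid.total == pytest.approx(1.0)

    def test_unknown_scheme(self):
        frame, _ = make_frame([[1.0, 1.0, 1.0]], ["NA"], box=(6.0, 6.0, 12.0))
        spec = GridSpec.from_box((6.0, 6.0, 12.0), 1.0)
        with pytest.raises(ValueError, match="scheme"):
            assign_charges(frame, spec, np.array([1.0]), scheme="TSC")

    def test_box_mismatch_rejected(self):
        frame, _ = make_frame([[1.0, 1.0, 1.0]], ["NA"], box=(6.0, 6.0, 12.0))
        spec = GridSpec.from_box((5.0, 6.0, 12.0), 1.0)
        with pytest.raises(ValueError, match="box"):
            assign_charges(frame, spec, np.array([1.0]))


class TestAveraging:
    def _two_frame_traj(self):
        box = (6.0, 6.0, 12.0)
        f1, species = make_frame([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]],
                                 ["NA", "CL"], box=box, time=0.0)
        f2, _ = make_frame([[1.5, 1.0, 1.0], [2.5, 2.0, 2.0]],
                           ["NA", "CL"], box=box, time=1.0)
        return Trajectory([f1, f2], species)

    def test_streaming_average_matches_per_frame_mean(self):
        traj = self._two_frame_traj()
        spec = GridSpec.from_box((6.0, 6.0, 12.0), 0.5)
        charges, ions = traj.charges(), traj.ion_mask()
        expected = time_average(
            [assign_charges(f, spec, charges, "CIC", ions) for f in traj]
        )
        got = time_averaged_charge_density(traj, spec, "CIC")
        np.testing.assert_allclose(got.values, expected.values, atol=1e-14)

    def test_frame_subset_selection(self):
        traj = self._two_frame_traj()
        spec = GridSpec.from_box((6.0, 6.0, 12.0), 0.5)
        only_last = time_averaged_charge_density(traj, spec, "CIC", [1])
        direct = assign_charges(traj.frames[1], spec, traj.charges(), "CIC",
                                traj.ion_mask())
        np.testing.assert_allclose(only_last.values, direct.values)

    def test_time_average_rejects_mixed_specs(self):
        spec_a = GridSpec.from_box((6.0, 6.0, 12.0), 0.5)
        spec_b = GridSpec.from_box((6.0, 6.0, 12.0), 1.0)
        g1 = ScalarGrid3D(spec_a, np.zeros(spec_a.dims), "charge_density")
        g2 = ScalarGrid3D(spec_b, np.zeros(spec_b.dims), "charge_density")
        with pytest.raises(ValueError, match="share"):
            time_average([g1, g2])


class TestProfiles:
    def test_axial_profile_integrates_to_total_charge(self, rng):
        box = (6.0, 6.0, 12.0)
        pos = rng.uniform(0, 1, size=(60, 3)) * np.asarray(box)
        frame, _ = make_frame(pos, ["NA"] * 30 + ["CL"] * 30, box=box)
        spec = GridSpec.from_box(box, 0.3)
        grid = assign_charges(frame, spec, np.array([1.0] * 30 + [-1.0] * 30))
        prof = axial_charge_profile(grid)
        lx, ly, _ = box
        integral = prof.values.sum() * lx * ly * prof.bin_width
        assert integral == pytest.approx(grid.total, abs=1e-12)

    def test_uniform_water_slab_density(self):
        # 1000 water beads uniformly in a box -> known mean mass density.
        rng = np.random.default_rng(3)
        box = (6.0, 6.0, 10.0)
        pos = rng.uniform(0, 1, size=(1000, 3)) * np.asarray(box)
        frame, species = make_frame(pos, ["W"] * 1000, box=box)
        traj = Trajectory([frame], species)
        prof = axial_mass_density_profile(traj, "W", bin_width=2.5)
        expected = 1000 * 72.0 / (6.0 * 6.0 * 10.0) * 1.66053906660
        assert prof.values.mean() == pytest.approx(expected, rel=1e-6)

    def test_empty_selection_rejected(self):
        frame, species = make_frame([[1.0, 1.0, 1.0]], ["NA"], box=(6.0, 6.0, 12.0))
        traj = Trajectory([frame], species)
        with pytest.raises(KeyError):
            axial_mass_density_profile(traj, "W")
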