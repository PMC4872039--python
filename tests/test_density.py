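"""Voxel density maps: counting, conservation, alignment, Q integration."""

import numpy as np
import pytest

from hydrokin.core import AtomSelection, MolecularSystem, Trajectory
from hydrokin.density import (
    AlignedWindow,
    AnchoredSphere,
    VoxelGrid,
    accumulate_density,
    box_mask,
    bulk_density,
    cylinder_mask,
    integrate_q,
    local_superpose_window,
    q_series,
    sliding_density_series,
    sphere_mask,
)


def water_system(oxygen_positions, with_h=True):
    """Waters with O (and optionally 2 H at ±0.6 Å along x)."""
    names, elements, coords, resids = [], [], [], []
    for i, pos in enumerate(oxygen_positions):
        names.append("O"); elements.append("O"); coords.append(list(pos)); resids.append(i + 1)
        if with_h:
            for dx in (-0.4, 0.4):
                names.append("H"); elements.append("H")
                coords.append([pos[0] + dx, pos[1], pos[2]]); resids.append(i + 1)
    n = len(names)
    return MolecularSystem(
        names=np.array(names), elements=np.array(elements),
        resids=np.array(resids), resnames=np.array(["HOH"] * n),
        chains=np.array(["W"] * n), record=np.array(["water"] * n),
        coords=np.array(coords, dtype=float),
    )


def static_window(system, n_frames=50):
    frames = np.repeat(system.coords[None], n_frames, axis=0)
    return AlignedWindow(system, frames, np.arange(float(n_frames)), system.coords.copy())


GRID = VoxelGrid.from_bounds((0.0, 0.0, 0.0), (10.0, 10.0, 10.0), 1.0)


class TestAccumulate:
    def test_stationary_water_contributes_ten_electrons(self):
        # O at the voxel center, both H offsets stay inside the same voxel
        sys_h = water_system([(5.5, 5.5, 5.5)])
        dmap = accumulate_density(static_window(sys_h), GRID)
        assert dmap.density[5, 5, 5] == 10.0
        assert dmap.density.sum() == 10.0

    def test_half_occupancy_gives_five_electrons(self):
        sys_ = water_system([(5.5, 5.5, 5.5)])
        frames = np.repeat(sys_.coords[None], 50, axis=0)
        frames[25:] += np.array([3.0, 0.0, 0.0])  # moves to a distant voxel
        window = AlignedWindow(sys_, frames, np.arange(50.0), frames.mean(axis=0))
        dmap = accumulate_density(window, GRID)
        assert dmap.density[5, 5, 5] == 5.0
        assert dmap.density[8, 5, 5] == 5.0

    def test_total_density_conserved(self):
        rng = np.random.default_rng(3)
        sys_ = water_system(rng.uniform(2, 8, size=(7, 3)))
        frames = rng.uniform(2, 8, size=(20, sys_.n_atoms, 3))
        window = AlignedWindow(sys_, frames, np.arange(20.0), frames.mean(axis=0))
        dmap = accumulate_density(window, GRID)
        assert dmap.density.sum() == 7 * 10.0  # exact: integer counting

    def test_matches_brute_force_histogram_bit_exactly(self):
        """Independent oracle: per-frame python loop over atoms and voxels."""
        rng = np.random.default_rng(11)
        sys_ = water_system(rng.uniform(0.5, 9.5, size=(30, 3)))  # 90 atoms
        frames = rng.uniform(-0.5, 10.5, size=(12, sys_.n_atoms, 3))
        window = AlignedWindow(sys_, frames, np.arange(12.0), frames.mean(axis=0))
        dmap = accumulate_density(window, GRID)

        electrons = {"O": 8, "H": 1}
        oracle = np.zeros(GRID.shape, dtype=np.int64)
        for frame in frames:
            for name, xyz in zip(sys_.names, frame):
                idx = np.floor(np.asarray(xyz)).astype(int)
                if np.all(idx >= 0) and np.all(idx < GRID.shape):
                    oracle[tuple(idx)] += electrons[name]
        assert np.array_equal(dmap.density, oracle / 12.0)

    def test_boundary_point_belongs_to_voxel_whose_low_edge_it_is(self):
        idx, ok = GRID.voxel_indices(np.array([[3.0, 0.0, 9.999]]))
        assert ok[0] and idx[0].tolist() == [3, 0, 9]
        _, ok2 = GRID.voxel_indices(np.array([[10.0, 5.0, 5.0]]))
        assert not ok2[0]  # the high edge is outside the half-open grid


class TestLocalSuperposition:
    def _anchored_scene(self):
        rng = np.random.default_rng(5)
        protein = rng.normal(size=(6, 3)) + np.array([5.0, 5.0, 5.0])
        waters = rng.uniform(3, 7, size=(4, 3))
        coords = np.vstack([protein, waters])
        n = len(coords)
        sys_ = MolecularSystem(
            names=np.array(["CA"] * 6 + ["O"] * 4),
            elements=np.array(["C"] * 6 + ["O"] * 4),
            resids=np.arange(1, n + 1),
            resnames=np.array(["ALA"] * 6 + ["HOH"] * 4),
            chains=np.array(["A"] * 6 + ["W"] * 4),
            record=np.array(["protein"] * 6 + ["water"] * 4),
            coords=coords,
        )
        return sys_

    def test_static_scene_identity(self):
        sys_ = self._anchored_scene()
        frames = np.repeat(sys_.coords[None], 5, axis=0)
        traj = Trajectory(sys_, frames, np.arange(5.0))
        anchor = AtomSelection(np.arange(6))
        window = local_superpose_window(traj, np.arange(5), anchor)
        assert np.allclose(window.frames, frames[0], atol=1e-12)
        assert np.allclose(window.avg_coords, frames[0], atol=1e-12)

    def test_rigidly_rotated_scene_realigned(self):
        from scipy.spatial.transform import Rotation

        sys_ = self._anchored_scene()
        rng = np.random.default_rng(9)
        frames = np.empty((6, sys_.n_atoms, 3))
        for k in range(6):
            rot = Rotation.random(rng=rng).as_matrix()
            frames[k] = sys_.coords @ rot.T + rng.normal(size=3)
        traj = Trajectory(sys_, frames, np.arange(6.0))
        window = local_superpose_window(traj, np.arange(6), AtomSelection(np.arange(6)))
        # co-rotating waters become time-constant after alignment
        assert np.allclose(window.frames, window.frames[0], atol=1e-9)

    def test_empty_window_rejected(self):
        sys_ = self._anchored_scene()
        traj = Trajectory(sys_, np.repeat(sys_.coords[None], 3, axis=0), np.arange(3.0))
        with pytest.raises(ValueError, match="empty"):
            local_superpose_window(traj, np.array([], dtype=int), AtomSelection(np.arange(6)))


class TestSlidingSeries:
    def _static_traj(self, n_frames):
        sys_ = water_system([(5.5, 5.5, 5.5)])
        anchor_sys = TestLocalSuperposition()._anchored_scene()
        coords = np.vstack([anchor_sys.coords, sys_.coords])
        merged = MolecularSystem(
            names=np.concatenate([anchor_sys.names, sys_.names]),
            elements=np.concatenate([anchor_sys.elements, sys_.elements]),
            resids=np.concatenate([anchor_sys.resids, sys_.resids + 100]),
            resnames=np.concatenate([anchor_sys.resnames, sys_.resnames]),
            chains=np.concatenate([anchor_sys.chains, sys_.chains]),
            record=np.concatenate([anchor_sys.record, sys_.record]),
            coords=coords,
        )
        frames = np.repeat(coords[None], n_frames, axis=0)
        return Trajectory(merged, frames, np.arange(float(n_frames)))

    def test_window_count_arithmetic(self):
        traj = self._static_traj(200)
        anchor = AtomSelection(np.arange(6))
        maps = sliding_density_series(traj, anchor, GRID, window_length=50, stride=1)
        assert len(maps) == 151

    def test_stride_equal_to_length_gives_one_map(self):
        traj = self._static_traj(60)
        anchor = AtomSelection(np.arange(6))
        maps = sliding_density_series(traj, anchor, GRID, window_length=60, stride=60)
        assert len(maps) == 1

    def test_statically_wet_pocket_series_constant(self):
        traj = self._static_traj(30)
        anchor = AtomSelection(np.arange(6))
        maps = sliding_density_series(traj, anchor, GRID, window_length=10, stride=5)
        for m in maps[1:]:
            assert np.allclose(m.density, maps[0].density, atol=1e-12)

    def test_window_longer_than_trajectory_rejected(self):
        traj = self._static_traj(20)
        with pytest.raises(ValueError, match="exceeds"):
            sliding_density_series(traj, AtomSelection(np.arange(6)), GRID,
                                   window_length=50, stride=1)


class TestQ:
    def test_fully_resident_waters_give_ten_electrons_each(self):
        sys_ = water_system([(4.4, 4.4, 4.4), (5.6, 5.6, 5.6), (4.4, 5.6, 4.4),
                             (5.6, 4.4, 5.6)])
        dmap = accumulate_density(static_window(sys_), GRID)
        mask = sphere_mask(GRID, (5.0, 5.0, 5.0), 3.0)
        assert integrate_q(dmap, mask) == 40.0

    def test_dry_region_zero(self):
        sys_ = water_system([(1.0, 1.0, 1.0)])
        dmap = accumulate_density(static_window(sys_), GRID)
        mask = sphere_mask(GRID, (8.0, 8.0, 8.0), 1.5)
        assert integrate_q(dmap, mask) == 0.0

    def test_partial_residence_scales_q(self):
        sys_ = water_system([(5.5, 5.5, 5.5)])
        frames = np.repeat(sys_.coords[None], 50, axis=0)
        frames[40:] += np.array([10.0, 0.0, 0.0])  # leaves grid for 20%
        window = AlignedWindow(sys_, frames, np.arange(50.0), frames.mean(axis=0))
        dmap = accumulate_density(window, GRID)
        mask = sphere_mask(GRID, (5.5, 5.5, 5.5), 2.0)
        assert integrate_q(dmap, mask) == pytest.approx(8.0)

    def test_additive_over_disjoint_masks_monotone_under_inclusion(self):
        rng = np.random.default_rng(13)
        sys_ = water_system(rng.uniform(1, 9, size=(10, 3)))
        dmap = accumulate_density(static_window(sys_, 5), GRID)
        m1 = box_mask(GRID, (0, 0, 0), (5, 10, 10))
        m2 = box_mask(GRID, (5, 0, 0), (10, 10, 10)) & ~m1
        whole = m1 | m2
        assert integrate_q(dmap, m1) + integrate_q(dmap, m2) == pytest.approx(
            integrate_q(dmap, whole)
        )
        assert integrate_q(dmap, m1) <= integrate_q(dmap, whole)

    def test_empty_mask_rejected(self):
        sys_ = water_system([(5.0, 5.0, 5.0)])
        dmap = accumulate_density(static_window(sys_), GRID)
        with pytest.raises(ValueError, match="empty"):
            integrate_q(dmap, np.zeros(GRID.shape, dtype=bool))

    def test_anchored_sphere_follows_average_structure(self):
        sys_ = water_system([(5.5, 5.5, 5.5)])
        window = static_window(sys_)
        dmap = accumulate_density(window, GRID)
        region = AnchoredSphere(anchor=AtomSelection(np.array([0])), radius=2.0)
        times, qs = q_series([dmap], region)
        assert qs[0] == 10.0


class TestBulkDensity:
    def test_empty_box_zero(self):
        sys_ = water_system([(1.0, 1.0, 1.0)])
        frames = np.repeat(sys_.coords[None], 3, axis=0) + 100.0  # off-grid
        window = AlignedWindow(sys_, frames, np.arange(3.0), frames.mean(axis=0))
        dmap = accumulate_density(window, GRID)
        assert bulk_density(dmap) == 0.0

    def test_doubling_waters_doubles_estimate(self):
        rng = np.random.default_rng(19)
        pos = rng.uniform(0.5, 9.5, size=(20, 3))
        d1 = accumulate_density(static_window(water_system(pos)), GRID)
        d2 = accumulate_density(static_window(water_system(np.vstack([pos, pos + 0.2]))), GRID)
        assert bulk_density(d2) == pytest.approx(2.0 * bulk_density(d1), rel=1e-6)

    def test_protein_exclusion_requires_bulk_voxels(self):
        sys_ = water_system([(5.0, 5.0, 5.0)])
        dmap = accumulate_density(static_window(sys_), GRID)
        protein = np.array([[5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="bulk"):
            bulk_density(dmap, protein, exclusion_distance=50.0)


def test_cylinder_mask_matches_geometry():
    grid = VoxelGrid.from_bounds((0, 0, 0), (10, 10, 10), 1.0)
    mask = cylinder_mask(grid, (5.0, 5.0, 1.0), (5.0, 5.0, 9.0), 2.0)
    centers = grid.voxel_centers()[mask.ravel()]
    radial = np.linalg.norm(centers[:, :2] - 5.0, axis=1)
    assert radial.max() <= 2.0
    assert mask.sum() > 0
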