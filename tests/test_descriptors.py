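"""ASA, hydration counting, change tables and site gauges."""

import numpy as np
import pytest

from hydrokin.core import MolecularSystem, Trajectory
from hydrokin.descriptors import (
    compute_asa,
    count_hydration_waters,
    gauge_d_hs1,
    gauge_d_hs2,
    residue_change_table,
)
from conftest import make_system


def shrake_rupley_oracle(coords, radii, probe, n_points=10_000):
    """Independent numerical ASA: dense Fibonacci sphere point counting."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n_points)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    r = np.sqrt(1.0 - z * z)
    phi = golden * k
    unit = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    out = np.empty(len(coords))
    for i, (c, ri) in enumerate(zip(coords, radii)):
        pts = c + (ri + probe) * unit
        accessible = np.ones(n_points, dtype=bool)
        for j, (cj, rj) in enumerate(zip(coords, radii)):
            if j == i:
                continue
            accessible &= np.linalg.norm(pts - cj, axis=1) > rj + probe
        out[i] = 4.0 * np.pi * (ri + probe) ** 2 * accessible.mean()
    return out


class TestComputeAsa:
    def test_isolated_carbon_is_full_sphere(self):
        sys_ = make_system([[0.0, 0.0, 0.0]], names=["CB"])
        asa = compute_asa(sys_)["asa"].iloc[0]
        assert asa == pytest.approx(4.0 * np.pi * (1.7 + 1.4) ** 2, rel=1e-6)

    def test_fully_enclosed_atom_is_zero(self):
        # central CB caged by 26 close carbons on a cube lattice
        offsets = [
            np.array([i, j, k], dtype=float)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        coords = [np.zeros(3)] + [2.0 * o / np.linalg.norm(o) for o in offsets]
        names = ["CB"] + ["CB"] * 26
        resids = [1] + [2] * 26
        sys_ = make_system(coords, names=names, resids=resids)
        table = compute_asa(sys_).set_index("resid")
        assert table.loc[1, "asa"] == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_system_matches_numerical_oracle(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        sys_ = make_system(coords, names=["CB", "CB"], resids=[1, 2],
                          elements=["C", "O"])
        table = compute_asa(sys_, point_number=960).set_index("resid")
        oracle = shrake_rupley_oracle(coords, np.array([1.7, 1.52]), 1.4)
        assert table.loc[1, "asa"] == pytest.approx(oracle[0], rel=0.01)
        assert table.loc[2, "asa"] == pytest.approx(oracle[1], rel=0.01)

    def test_rigid_motion_invariance(self, template):
        from scipy.spatial.transform import Rotation

        # point-sampled ASA is rotation invariant only up to sampling noise,
        # which shrinks with the point count
        base = compute_asa(template, point_number=5000)["asa"].to_numpy()
        rot = Rotation.from_euler("xyz", [30, 60, -15], degrees=True).as_matrix()
        moved = template.with_coords(template.coords @ rot.T + [5.0, -3.0, 2.0])
        rotated = compute_asa(moved, point_number=5000)["asa"].to_numpy()
        assert np.allclose(rotated, base, atol=2.0)

    def test_approaching_atom_cannot_increase_asa(self):
        asa_prev = np.inf
        for dist in (8.0, 5.0, 4.0, 3.0, 2.0):
            sys_ = make_system([[0.0, 0.0, 0.0], [dist, 0.0, 0.0]],
                              names=["CB", "CB"], resids=[1, 2])
            asa = compute_asa(sys_).set_index("resid").loc[1, "asa"]
            assert asa <= asa_prev + 1e-9
            asa_prev = asa

    def test_unknown_element_reported(self):
        sys_ = make_system([[0.0, 0.0, 0.0]], names=["XX"], elements=["Q"])
        with pytest.raises(ValueError, match="Q"):
            compute_asa(sys_)


def water(resid, x, y, z):
    return dict(name="O", element="O", resid=resid, resname="HOH", record="water",
                coords=[x, y, z])


def build_frame(entries):
    return make_system(
        [e["coords"] for e in entries],
        names=[e["name"] for e in entries],
        elements=[e["element"] for e in entries],
        resids=[e["resid"] for e in entries],
        resnames=[e.get("resname", "ALA") for e in entries],
        record=[e.get("record", "protein") for e in entries],
    )


class TestHydrationCount:
    def make_residue_frame(self, *waters_xyz):
        entries = [
            dict(name="CA", element="C", resid=1, coords=[0.0, 0.0, 0.0]),
            dict(name="CB", element="C", resid=1, coords=[1.5, 0.0, 0.0]),
            dict(name="CG", element="C", resid=1, coords=[3.0, 0.0, 0.0]),
        ]
        entries += [water(100 + i, *xyz) for i, xyz in enumerate(waters_xyz)]
        return build_frame(entries)

    def test_inside_cutoff_counts(self):
        frame = self.make_residue_frame([1.5, 3.4, 0.0])
        assert count_hydration_waters(frame, 1) == 1

    def test_outside_cutoff_ignored(self):
        frame = self.make_residue_frame([1.5, 3.6, 0.0])
        assert count_hydration_waters(frame, 1) == 0

    def test_molecule_level_dedup(self):
        # three waters, each within the cutoff of both CB and CG
        frame = self.make_residue_frame(
            [2.25, 1.0, 0.0], [2.25, -1.0, 0.0], [2.25, 0.0, 1.0]
        )
        assert count_hydration_waters(frame, 1) == 3

    def test_backbone_contacts_do_not_count(self):
        # water near CA only (backbone) is not a side-chain contact
        frame = self.make_residue_frame([-3.0, 0.5, 0.0])
        assert count_hydration_waters(frame, 1) == 0

    def test_glycine_warns_and_returns_zero(self):
        entries = [dict(name="CA", element="C", resid=7, resname="GLY",
                        coords=[0.0, 0.0, 0.0]), water(100, 1.0, 0.0, 0.0)]
        frame = build_frame(entries)
        with pytest.warns(UserWarning, match="side-chain"):
            assert count_hydration_waters(frame, 7) == 0

    def test_matches_brute_force_all_pairs_scan(self, template):
        rng = np.random.default_rng(17)
        waters = [water(500 + i, *xyz) for i, xyz in
                  enumerate(rng.uniform(-5, 20, size=(60, 3)))]
        entries = []
        for i in range(template.n_atoms):
            entries.append(dict(name=template.names[i], element=template.elements[i],
                                resid=int(template.resids[i]),
                                resname=template.resnames[i], record="protein",
                                coords=template.coords[i]))
        frame = build_frame(entries + waters)
        from hydrokin.core import BACKBONE_ATOMS

        for resid in (89, 92, 340):
            side = frame.coords[
                (frame.resids == resid) & (frame.record == "protein")
                & ~np.isin(frame.names, list(BACKBONE_ATOMS))
            ]
            wxyz = np.array([w["coords"] for w in waters])
            brute = sum(
                1 for w in wxyz
                if np.any(np.linalg.norm(side - w, axis=1) <= 3.5)
            )
            assert count_hydration_waters(frame, resid) == brute


class TestChangeTable:
    def _toy_trajectory(self, closed_scale):
        """Two-residue chain plus one water; closed frames shrink exposure by
        pulling a cage of atoms around residue 2."""
        base = [
            dict(name="CA", element="C", resid=1, coords=[0.0, 0.0, 0.0]),
            dict(name="CB", element="C", resid=1, coords=[1.6, 0.0, 0.0]),
            dict(name="CA", element="C", resid=2, coords=[10.0, 0.0, 0.0]),
            dict(name="CB", element="C", resid=2, coords=[11.6, 0.0, 0.0]),
            water(100, 1.6, 3.0, 0.0),
        ]
        open_frame = build_frame(base)
        closed = [dict(e, coords=list(e["coords"])) for e in base]
        closed[4]["coords"] = [1.6, 10.0, 0.0]  # water leaves residue 1
        closed_frame = build_frame(closed)
        frames = np.stack([open_frame.coords, closed_frame.coords])
        traj = Trajectory(open_frame, frames, times=[0.0, 1.0])
        return traj

    def test_sign_and_exclusion_rules(self):
        traj = self._toy_trajectory(0.5)
        table = residue_change_table(
            traj, np.array(["open", "closed"])
        ).set_index("resid")
        # identical coordinates in both frames -> R_asa = 0
        assert table.loc[2, "r_asa"] == pytest.approx(0.0, abs=1e-9)
        # residue 1 loses its only hydration water on closure -> R_wat = -1
        assert table.loc[1, "r_wat"] == pytest.approx(-1.0)

    def test_halved_asa_gives_minus_half(self):
        # direct check of the ratio convention on synthetic means
        open_mean, closed_mean = 40.0, 20.0
        assert (closed_mean - open_mean) / open_mean == -0.5

    def test_buried_residue_excluded(self):
        traj = self._toy_trajectory(1.0)
        # shrink probe exposure by burying residue 2 under a dense cage
        table = residue_change_table(traj, np.array(["open", "closed"]),
                                     burial_cutoff=1e6).set_index("resid")
        assert bool(table.loc[1, "excluded"]) and bool(table.loc[2, "excluded"])
        assert np.isnan(table.loc[1, "r_asa"])

    def test_requires_both_ensembles(self):
        traj = self._toy_trajectory(1.0)
        with pytest.raises(ValueError, match="open"):
            residue_change_table(traj, np.array(["open", "intermediate"]))

    def test_frame_order_independence(self):
        traj = self._toy_trajectory(0.5)
        labels = np.array(["open", "closed"])
        t1 = residue_change_table(traj, labels)
        traj2 = Trajectory(traj.topology, traj.frames[::-1].copy(), times=[0.0, 1.0])
        t2 = residue_change_table(traj2, labels[::-1])
        assert np.allclose(
            t1[["r_asa", "r_wat"]].fillna(0).to_numpy(),
            t2[["r_asa", "r_wat"]].fillna(0).to_numpy(),
        )


class TestGauges:
    def test_jaw_distance_uses_nearer_ring_hydrogen(self):
        entries = [
            dict(name="HD1", element="H", resid=340, resname="PHE", coords=[0.0, 0.0, 6.0]),
            dict(name="HE1", element="H", resid=340, resname="PHE", coords=[0.0, 0.0, 9.0]),
            dict(name="CD1", element="C", resid=89, resname="TRP", coords=[0.0, 0.0, 0.0]),
            dict(name="CG", element="C", resid=92, resname="TRP", coords=[0.0, 0.0, 0.0]),
        ]
        assert gauge_d_hs1(build_frame(entries)) == pytest.approx(6.0)

    def test_coincident_jaws_degenerate_zero(self):
        entries = [
            dict(name="HD1", element="H", resid=340, resname="PHE", coords=[1.0, 1.0, 1.0]),
            dict(name="CD1", element="C", resid=89, resname="TRP", coords=[1.0, 1.0, 1.0]),
            dict(name="CG", element="C", resid=92, resname="TRP", coords=[1.0, 1.0, 1.0]),
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            assert gauge_d_hs1(build_frame(entries)) == 0.0

    def test_missing_hydrogens_is_explicit_error(self):
        entries = [
            dict(name="CZ", element="C", resid=340, resname="PHE", coords=[0.0, 0.0, 6.0]),
            dict(name="CD1", element="C", resid=89, resname="TRP", coords=[0.0, 0.0, 0.0]),
            dict(name="CG", element="C", resid=92, resname="TRP", coords=[0.0, 0.0, 0.0]),
        ]
        with pytest.raises(ValueError, match="hydrogen"):
            gauge_d_hs1(build_frame(entries))

    def test_crevice_stretch_series_reproduces_construction(self):
        for d in np.linspace(9.5, 11.5, 5):
            entries = [
                dict(name="CA", element="C", resid=190, coords=[0.0, 0.0, 0.0]),
                dict(name="OE1", element="O", resid=354, resname="GLU",
                     coords=[d, 0.0, 0.0]),
            ]
            assert gauge_d_hs2(build_frame(entries)) == pytest.approx(d, abs=1e-12)

    def test_missing_atom_named_in_error(self):
        entries = [dict(name="CA", element="C", resid=190, coords=[0.0, 0.0, 0.0])]
        with pytest.raises(ValueError, match="OE1"):
            gauge_d_hs2(build_frame(entries))
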