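"""Occupancy grids, near-residue water counts, contacts, ligand RMSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrswitch import (
    BWIndex,
    BWTable,
    GridSpec,
    GpcrSwitchError,
    TopologyError,
    TopologyMap,
    Trajectory,
    contact_frequency,
    ligand_rmsd,
    water_occupancy,
    waters_near,
)
from gpcrswitch._geom import random_rotation
from gpcrswitch.synth import gen_solvated_box


def _ligand_system(n_prot=6, n_lig=3):
    """Tiny receptor+ligand topology for contact/RMSD tests."""
    rows = []
    for i in range(n_prot):
        rows.append(("CA", "ALA", 10 + i, "C"))
    for j in range(n_lig):
        rows.append((f"C{j+1}", "LIG", 900, "C"))
    atoms = pd.DataFrame(rows, columns=["name", "resname", "resseq", "element"])
    bw = BWTable(((BWIndex(3, 50), 10, "ALA"),))
    return TopologyMap(
        atoms=atoms, bw=bw, ligand_indices=np.arange(n_prot, n_prot + n_lig)
    )


def _base_coords(top):
    coords = np.zeros((top.n_atoms, 3))
    n_prot = len(top.atoms) - len(top.ligand_indices)
    for i in range(n_prot):
        # non-collinear receptor frame so superposition is well-posed
        coords[i] = (np.cos(1.7 * i), 4.0 * i, np.sin(1.7 * i))
    coords[0] = (0.0, 0.0, 0.0)
    for k, j in enumerate(top.ligand_indices):
        coords[j] = (10.0, 2.0 * k, 0.0)
    return coords


class TestOccupancyGrid:
    def test_static_water_counts_every_frame(self):
        traj, top, _ = gen_solvated_box(density=0.0, n_frames=10, seed=0)
        # place a single crafted water by hand: reuse marker-only system
        atoms = top.atoms.copy()
        atoms.loc[len(atoms)] = ("O", "HOH", 99, "O")
        top2 = TopologyMap(atoms=atoms, bw=top.bw,
                           water_oxygen_indices=np.array([1]))
        coords = np.zeros((10, 2, 3))
        coords[:, 0] = 10.0
        coords[:, 1] = (2.5, 2.5, 2.5)  # voxel center of voxel (2,2,2)
        traj = Trajectory(coords=coords, times=np.arange(10.0))
        grid = water_occupancy(traj, top2, GridSpec((0, 0, 0), 1.0, (5, 5, 5)))
        assert grid.counts[2, 2, 2] == 10
        assert grid.counts.sum() == 10

    def test_counts_conserve_inbounds_observations(self):
        traj, top, _ = gen_solvated_box(box=(15.0, 15.0, 15.0), n_frames=50, seed=2)
        grid = water_occupancy(traj, top, GridSpec((0, 0, 0), 1.0, (15, 15, 15)))
        n_waters = len(top.water_oxygen_indices)
        assert grid.counts.sum() == 50 * n_waters  # all placements in-bounds

    def test_bulk_relative_mean_near_one(self):
        traj, top, _ = gen_solvated_box(n_frames=1000, seed=5)
        grid = water_occupancy(traj, top, GridSpec((0, 0, 0), 1.0, (20, 20, 20)))
        mean = grid.normalized("bulk_relative").mean()
        n_total = grid.counts.sum()
        assert abs(mean - 1.0) < 3.0 / np.sqrt(n_total) + 1e-3
        assert grid.normalized("per_frame").sum() == pytest.approx(n_total / 1000)

    def test_empty_water_set_gives_zero_grid(self):
        traj, top, _ = gen_solvated_box(density=0.0, n_frames=5, seed=0)
        grid = water_occupancy(traj, top, GridSpec((0, 0, 0), 1.0, (4, 4, 4)))
        assert grid.counts.sum() == 0

    def test_zero_volume_grid_rejected(self):
        with pytest.raises(GpcrSwitchError):
            GridSpec((0, 0, 0), 0.0, (4, 4, 4))

    def test_dx_export_is_parseable(self, tmp_path):
        traj, top, _ = gen_solvated_box(n_frames=5, seed=1)
        grid = water_occupancy(traj, top, GridSpec((0, 0, 0), 2.0, (10, 10, 10)))
        path = tmp_path / "occ.dx"
        grid.to_dx(path, mode="per_frame")
        text = path.read_text()
        assert "gridpositions counts 10 10 10" in text
        values = []
        for line in text.splitlines():
            parts = line.split()
            if parts and all(p.replace(".", "").replace("-", "").replace("e", "")
                             .replace("+", "").isdigit() for p in parts):
                values.extend(float(p) for p in parts)
        assert sum(values) == pytest.approx(grid.normalized("per_frame").sum(), rel=1e-4)


class TestWatersNear:
    def test_pinned_fraction_recovered(self):
        traj, top, pinned = gen_solvated_box(
            n_frames=500, seed=6, pinned_fraction=0.7
        )
        mean = waters_near(traj, top, "5.36", "CA", 2.0)
        assert mean == pytest.approx(pinned.mean(), abs=1e-12)
        sigma = np.sqrt(0.7 * 0.3 / 500)
        assert abs(mean - 0.7) < 3 * sigma

    def test_no_waters_gives_zero(self):
        traj, top, _ = gen_solvated_box(density=0.0, n_frames=10, seed=0)
        assert waters_near(traj, top, "5.36", "CA", 2.0) == 0.0

    def test_two_constant_waters(self):
        traj, top, _ = gen_solvated_box(density=0.0, n_frames=4, seed=0)
        atoms = top.atoms.copy()
        atoms.loc[len(atoms)] = ("O", "HOH", 98, "O")
        atoms.loc[len(atoms)] = ("O", "HOH", 99, "O")
        top2 = TopologyMap(atoms=atoms, bw=top.bw,
                           water_oxygen_indices=np.array([1, 2]))
        coords = np.zeros((4, 3, 3))
        coords[:, 0] = 10.0  # marker
        coords[:, 1] = (10.0, 10.0, 11.0)
        coords[:, 2] = (10.0, 11.5, 10.0)
        traj = Trajectory(coords=coords, times=np.arange(4.0))
        assert waters_near(traj, top2, "5.36", "CA", 2.0) == 2.0


class TestContactFrequency:
    def test_persistent_contact_scores_one(self):
        top = _ligand_system()
        coords = _base_coords(top)
        coords[top.ligand_indices[0]] = (2.9, 0.0, 0.0)  # 2.9 Å from residue 10
        traj = Trajectory(coords=np.tile(coords, (8, 1, 1)),
                          times=np.arange(8.0))
        table = contact_frequency(traj, top, cutoff=3.0)
        assert table.set_index("resseq").loc[10, "frequency"] == 1.0

    def test_never_within_cutoff_scores_zero(self):
        top = _ligand_system()
        coords = _base_coords(top)
        coords[top.ligand_indices, 0] = 3.5  # nearest approach 3.5 Å
        coords[top.ligand_indices, 1] = 0.0
        traj = Trajectory(coords=coords[None], times=np.array([0.0]))
        table = contact_frequency(traj, top, cutoff=3.0, top_n=None)
        assert (table["frequency"] == 0.0).all()

    def test_half_frames_in_contact(self):
        top = _ligand_system()
        near = _base_coords(top)
        near[top.ligand_indices[0]] = (2.0, 0.0, 0.0)
        far = _base_coords(top)
        far[top.ligand_indices[0]] = (20.0, 0.0, 0.0)
        coords = np.array([near, far, near, far])
        traj = Trajectory(coords=coords, times=np.arange(4.0))
        table = contact_frequency(traj, top, cutoff=3.0)
        assert table.set_index("resseq").loc[10, "frequency"] == 0.5

    def test_monotone_in_cutoff(self, rng):
        top = _ligand_system()
        coords = _base_coords(top) + rng.normal(scale=2.0, size=(20, top.n_atoms, 3))
        traj = Trajectory(coords=coords, times=np.arange(20.0))
        freqs = []
        for cutoff in (2.0, 3.0, 5.0, 8.0):
            t = contact_frequency(traj, top, cutoff=cutoff, top_n=None)
            freqs.append(t.set_index("resseq")["frequency"].sort_index())
        for a, b in zip(freqs, freqs[1:]):
            assert (b >= a - 1e-12).all()

    def test_missing_ligand_is_error(self):
        traj, top, _ = gen_solvated_box(density=0.0, n_frames=2, seed=0)
        with pytest.raises(TopologyError):
            contact_frequency(traj, top)


class TestLigandRMSD:
    def test_identical_frame_is_zero(self):
        top = _ligand_system()
        ref = _base_coords(top)
        traj = Trajectory(coords=ref[None], times=np.array([0.0]))
        per_frame, mean = ligand_rmsd(traj, top, ref, fit_indices=range(6))
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_rigid_ligand_offset(self):
        top = _ligand_system()
        ref = _base_coords(top)
        frame = ref.copy()
        frame[top.ligand_indices] += (0.0, 0.0, 1.0)
        traj = Trajectory(coords=frame[None], times=np.array([0.0]))
        _, mean = ligand_rmsd(traj, top, ref, fit_indices=range(6))
        assert mean == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_formula(self, rng):
        top = _ligand_system()
        ref = _base_coords(top)
        coords = np.tile(ref, (10, 1, 1))
        coords[:, top.ligand_indices, :] += rng.normal(scale=0.5, size=(10, 3, 3))
        traj = Trajectory(coords=coords, times=np.arange(10.0))
        per_frame, _ = ligand_rmsd(traj, top, ref, fit_indices=range(6))
        for f in range(10):
            dev = coords[f, top.ligand_indices] - ref[top.ligand_indices]
            brute = np.sqrt(np.mean(np.sum(dev**2, axis=1)))
            assert per_frame[f] == pytest.approx(brute, abs=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_global_rigid_motion(self, seed):
        """Receptor superposition removes any global rigid motion."""
        rng = np.random.default_rng(seed)
        top = _ligand_system()
        ref = _base_coords(top)
        frame = ref.copy()
        frame[top.ligand_indices] += rng.normal(scale=0.5, size=(3, 3))
        R = random_rotation(rng)
        t = rng.uniform(-30, 30, size=3)
        moved = frame @ R.T + t
        traj = Trajectory(
            coords=np.stack([frame, moved]), times=np.array([0.0, 1.0])
        )
        per_frame, _ = ligand_rmsd(traj, top, ref, fit_indices=range(6))
        assert per_frame[1] == pytest.approx(per_frame[0], abs=1e-9)
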