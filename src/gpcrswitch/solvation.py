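"""Water-occupancy grids, near-residue water counts, ligand contacts and RMSD.

Water positions are represented by the oxygen atom.  Occupancy grids count
water-oxygen observations per voxel over all frames; ``bulk_relative``
normalization divides the per-frame voxel occupancy by the number of waters a
voxel would hold at the bulk density of pure water (0.0334 Å⁻³ at 300 K), so
a value of 1.0 means bulk-like hydration.

Ligand contacts use heavy atoms only (robust to hydrogen placement): a
residue is in contact in a frame if any of its heavy atoms is within the
cutoff of any ligand heavy atom.  Ligand RMSD is computed after superposing
the receptor Cα set onto the reference, without re-fitting the ligand, so it
reports genuine motion of the ligand in the receptor frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geom import apply_rigid, kabsch
from .errors import GpcrSwitchError, TopologyError
from .structure import WATER_RESNAMES, BWIndex, TopologyMap, Trajectory, select_atom

#: number density of pure water at 300 K, waters per Å³
BULK_WATER_DENSITY = 0.0334


@dataclass(frozen=True)
class GridSpec:
    """A regular 3D voxel grid: origin (Å), voxel spacing (Å), node counts."""

    origin: tuple[float, float, float]
    spacing: float = 1.0
    shape: tuple[int, int, int] = (10, 10, 10)

    def __post_init__(self) -> None:
        if self.spacing <= 0 or any(n < 1 for n in self.shape):
            raise GpcrSwitchError("grid must have positive spacing and shape")

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing**3)

    def edges(self) -> list[np.ndarray]:
        return [
            self.origin[k] + self.spacing * np.arange(self.shape[k] + 1)
            for k in range(3)
        ]


@dataclass
class OccupancyGrid:
    """Raw water-observation counts per voxel with normalization views."""

    spec: GridSpec
    counts: np.ndarray
    n_frames: int

    def normalized(self, mode: str = "raw_counts") -> np.ndarray:
        if mode == "raw_counts":
            return self.counts.astype(float)
        if mode == "per_frame":
            return self.counts / self.n_frames
        if mode == "bulk_relative":
            expected = BULK_WATER_DENSITY * self.spec.voxel_volume
            return self.counts / (self.n_frames * expected)
        raise GpcrSwitchError(f"unknown normalization {mode!r}")

    def to_dx(self, path: "str | Path", mode: str = "per_frame") -> None:
        """Write the grid in OpenDX format (as consumed by VMD/PyMOL)."""
        data = self.normalized(mode)
        nx, ny, nz = self.spec.shape
        d = self.spec.spacing
        ox, oy, oz = self.spec.origin
        # voxel-center origin for visualization
        with open(path, "w") as fh:
            fh.write(f"# water occupancy grid, normalization={mode}\n")
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(f"origin {ox + d / 2:.4f} {oy + d / 2:.4f} {oz + d / 2:.4f}\n")
            fh.write(f"delta {d:.4f} 0 0\ndelta 0 {d:.4f} 0\ndelta 0 0 {d:.4f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
            )
            flat = data.ravel(order="C")
            for i in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "density" class field\n')


def water_occupancy(traj: Trajectory, top: TopologyMap, spec: GridSpec) -> OccupancyGrid:
    """Count water-oxygen observations per voxel over all frames."""
    widx = top.water_oxygen_indices
    counts = np.zeros(spec.shape, dtype=np.int64)
    if len(widx) > 0:
        edges = spec.edges()
        pts = traj.coords[:, widx, :].reshape(-1, 3)
        h, _ = np.histogramdd(pts, bins=edges)
        counts = h.astype(np.int64)
    return OccupancyGrid(spec=spec, counts=counts, n_frames=traj.n_frames)


def waters_near(
    traj: Trajectory,
    top: TopologyMap,
    bw: "BWIndex | str",
    atom_role: str = "CA",
    cutoff: float = 2.0,
) -> float:
    """Mean number of water oxygens within ``cutoff`` Å of a selected atom."""
    idx = select_atom(top, bw, atom_role)
    if not isinstance(idx, (int, np.integer)):
        raise GpcrSwitchError("waters_near requires a single-atom role")
    widx = top.water_oxygen_indices
    if len(widx) == 0:
        return 0.0
    d = np.linalg.norm(
        traj.coords[:, widx, :] - traj.coords[:, [idx], :], axis=-1
    )
    return float(np.mean(np.count_nonzero(d <= cutoff, axis=1)))


def contact_frequency(
    traj: Trajectory,
    top: TopologyMap,
    cutoff: float = 3.0,
    top_n: "int | None" = 10,
) -> pd.DataFrame:
    """Per-residue fraction of frames with a ligand contact.

    A contact exists when any ligand heavy atom is within ``cutoff`` Å of any
    heavy atom of the residue.  Returns a table sorted by descending
    frequency (top ``top_n`` rows; ``None`` for all residues with nonzero
    frequency), with the BW index where the numbering table covers it.
    """
    lig = top.heavy(top.ligand_indices)
    if len(lig) == 0:
        raise TopologyError("no ligand atoms in topology: contact analysis impossible")
    is_water = top.atoms["resname"].isin(WATER_RESNAMES)
    prot_mask = (
        (top.atoms["element"] != "H")
        & ~top.atoms.index.isin(top.ligand_indices)
        & ~is_water
    )
    prot_idx = top.atoms.index[prot_mask].to_numpy()
    prot_res = top.atoms.loc[prot_idx, "resseq"].to_numpy()
    resseqs = np.unique(prot_res)
    hits = {r: 0 for r in resseqs}
    for f in range(traj.n_frames):
        tree = cKDTree(traj.coords[f, lig, :])
        near = tree.query_ball_point(traj.coords[f, prot_idx, :], r=cutoff)
        touched = {prot_res[i] for i, lst in enumerate(near) if lst}
        for r in touched:
            hits[r] += 1
    # reverse lookup resseq -> BW string where the table covers it
    bw_of = {resseq: str(bw) for bw, resseq, _ in top.bw.entries}
    resname_of = top.atoms.groupby("resseq")["resname"].first()
    rows = [
        {
            "resseq": int(r),
            "resname": str(resname_of.get(r, "")),
            "bw_index": bw_of.get(int(r), ""),
            "frequency": hits[r] / traj.n_frames,
        }
        for r in resseqs
    ]
    df = pd.DataFrame(rows).sort_values(
        ["frequency", "resseq"], ascending=[False, True], ignore_index=True
    )
    df.attrs["cutoff_A"] = cutoff
    if top_n is not None:
        df = df.head(top_n).reset_index(drop=True)
    return df


def ligand_rmsd(
    traj: Trajectory,
    top: TopologyMap,
    reference_coords: np.ndarray,
    fit_indices: "Sequence[int] | None" = None,
) -> tuple[np.ndarray, float]:
    """Ligand heavy-atom RMSD per frame after receptor-Cα superposition.

    Each frame is least-squares superposed onto the reference using
    ``fit_indices`` (default: all receptor Cα); the ligand RMSD is then
    computed without further fitting.  Returns (per-frame RMSD, mean).
    """
    reference_coords = np.asarray(reference_coords, dtype=float)
    if reference_coords.shape != (top.n_atoms, 3):
        raise TopologyError("reference coordinate array does not match topology")
    lig = top.heavy(top.ligand_indices)
    if len(lig) == 0:
        raise TopologyError("no ligand atoms in topology")
    fit = (
        np.asarray(fit_indices, dtype=int)
        if fit_indices is not None
        else top.protein_ca_indices()
    )
    if len(fit) < 3:
        raise GpcrSwitchError("need >= 3 fitting atoms for superposition")
    ref_lig = reference_coords[lig]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t = kabsch(traj.coords[f, fit, :], reference_coords[fit])
        moved = apply_rigid(traj.coords[f, lig, :], R, t)
        out[f] = np.sqrt(np.mean(np.sum((moved - ref_lig) ** 2, axis=1)))
    return out, float(np.mean(out))
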