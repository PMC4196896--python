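"""Topology and trajectory data model keyed by Ballesteros–Weinstein numbering.

Every analysis in this package selects atoms through :class:`TopologyMap`,
which couples a parsed structure (atom names, residue numbers, elements) to a
:class:`BWTable` mapping generic helix positions such as ``6.44`` to author
residue numbers.  Conventions used throughout: coordinates in Å, times in ps,
energies in kcal/mol, angles in degrees; atom indices are 0-based internally
while residue numbers are always the author/PDB numbering.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NumberingError, TopologyError, TrajectoryError

#: residue names recognised as water; only the oxygen atom is tracked
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

#: residue names treated as ligand by default (synthetic fixtures use "LIG")
DEFAULT_LIGAND_RESNAMES = frozenset({"LIG", "ERM", "LSD"})

_BW_RE = re.compile(r"^([1-8])\.(\d{1,2})$")


@dataclass(frozen=True, order=True)
class BWIndex:
    """A generic residue index ``helix.position`` (e.g. ``6.44``).

    By convention the most conserved residue of helix H is H.50; positions
    count along the helix so that sequence numbers and generic positions move
    in lockstep.
    """

    helix: int
    position: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 8:
            raise NumberingError(f"helix must be 1..8, got {self.helix}")
        if not 1 <= self.position <= 99:
            raise NumberingError(f"position must be 1..99, got {self.position}")

    @classmethod
    def parse(cls, text: str) -> "BWIndex":
        m = _BW_RE.match(str(text).strip())
        if not m:
            raise NumberingError(f"cannot parse BW index {text!r} (expected 'H.PP')")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.helix}.{self.position}"


def _as_bw(bw: "BWIndex | str") -> BWIndex:
    return bw if isinstance(bw, BWIndex) else BWIndex.parse(bw)


@dataclass(frozen=True)
class BWTable:
    """Mapping of BW indices to (residue number, residue name) for one receptor.

    Invariant: within a helix, residue numbers are strictly increasing and
    consecutive with the generic positions, i.e. resseq(p2) - resseq(p1) =
    p2 - p1 for any two listed positions of the same helix.
    """

    entries: tuple[tuple[BWIndex, int, str], ...]
    receptor: str = ""

    def __post_init__(self) -> None:
        seen: dict[BWIndex, int] = {}
        for bw, resseq, _ in self.entries:
            if bw in seen:
                raise NumberingError(f"duplicate BW index {bw}")
            seen[bw] = resseq
        by_helix: dict[int, list[tuple[int, int]]] = {}
        for bw, resseq, _ in self.entries:
            by_helix.setdefault(bw.helix, []).append((bw.position, resseq))
        for helix, pairs in by_helix.items():
            pairs.sort()
            for (p1, r1), (p2, r2) in zip(pairs, pairs[1:]):
                if r2 - r1 != p2 - p1:
                    raise NumberingError(
                        f"helix {helix}: residues {r1}..{r2} not consecutive with "
                        f"positions {p1}..{p2}"
                    )

    def __contains__(self, bw: object) -> bool:
        bw = _as_bw(bw)  # type: ignore[arg-type]
        return any(e[0] == bw for e in self.entries)

    def _entry(self, bw: BWIndex | str) -> tuple[BWIndex, int, str]:
        bw = _as_bw(bw)
        for e in self.entries:
            if e[0] == bw:
                return e
        # fall back to the consecutive-numbering rule within the helix
        for e in self.entries:
            if e[0].helix == bw.helix:
                return (bw, e[1] + (bw.position - e[0].position), "")
        raise NumberingError(f"BW index {bw} not covered by table (no helix anchor)")

    def resseq(self, bw: BWIndex | str) -> int:
        """Residue number for ``bw``; positions missing from the table are
        filled in by the consecutive-numbering rule from any listed anchor of
        the same helix."""
        return self._entry(bw)[1]

    def resname(self, bw: BWIndex | str) -> str:
        return self._entry(bw)[2]

    @classmethod
    def from_anchor(
        cls,
        anchor: BWIndex | str,
        anchor_resseq: int,
        resnames: "dict[str, str] | None" = None,
        receptor: str = "",
        extra: "Iterable[tuple[BWIndex | str, int, str]]" = (),
    ) -> "BWTable":
        """Build a table from one anchor per helix plus optional named entries.

        ``resnames`` maps BW strings to residue names; unnamed positions are
        resolved on demand through the consecutive rule.
        """
        anchor = _as_bw(anchor)
        entries = [(anchor, anchor_resseq, (resnames or {}).get(str(anchor), ""))]
        for bw_str, name in (resnames or {}).items():
            bw = _as_bw(bw_str)
            if bw == anchor:
                continue
            if bw.helix != anchor.helix:
                raise NumberingError(
                    f"{bw} is not on anchor helix {anchor.helix}; use `extra`"
                )
            entries.append((bw, anchor_resseq + bw.position - anchor.position, name))
        entries.extend((_as_bw(b), r, n) for b, r, n in extra)
        return cls(tuple(entries), receptor=receptor)

    @classmethod
    def from_tsv(cls, path: "str | Path", receptor: str = "") -> "BWTable":
        """Read a table from TSV with columns bw_index, resseq, resname."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"bw_index", "resseq", "resname"}
        if not required.issubset(df.columns):
            raise NumberingError(
                f"BW table {path} must have columns {sorted(required)}"
            )
        entries = tuple(
            (BWIndex.parse(row.bw_index), int(row.resseq), str(row.resname))
            for row in df.itertuples()
        )
        return cls(entries, receptor=receptor)

    def to_tsv(self, path: "str | Path") -> None:
        df = pd.DataFrame(
            [(str(bw), resseq, resname) for bw, resseq, resname in self.entries],
            columns=["bw_index", "resseq", "resname"],
        )
        df.to_csv(path, sep="\t", index=False)


def _guess_element(atom_name: str) -> str:
    """Element from a PDB atom name (leading digits stripped; H variants → H)."""
    name = atom_name.strip()
    name = re.sub(r"^\d+", "", name)
    if not name:
        return "X"
    if name[0] == "H" or (len(name) > 1 and name[0].isdigit() and name[1] == "H"):
        return "H"
    return name[0].upper()


@dataclass
class TopologyMap:
    """Atom bookkeeping: names, residues, elements, BW mapping, special sets.

    ``atoms`` is a DataFrame indexed by 0-based atom index with columns
    ``name, resname, resseq, element``.
    """

    atoms: pd.DataFrame
    bw: BWTable
    ligand_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    water_oxygen_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )
    source: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atoms_of_residue(self, resseq: int) -> pd.DataFrame:
        return self.atoms[self.atoms["resseq"] == resseq]

    def resolve_bw(self, bw: BWIndex | str) -> pd.DataFrame:
        bw = _as_bw(bw)
        sub = self.atoms_of_residue(self.bw.resseq(bw))
        if len(sub) == 0:
            raise TopologyError(f"BW index {bw} resolves to no atoms in topology")
        return sub

    def heavy(self, indices: np.ndarray) -> np.ndarray:
        els = self.atoms.loc[indices, "element"].to_numpy()
        return np.asarray(indices)[els != "H"]

    def protein_ca_indices(self) -> np.ndarray:
        mask = (
            (self.atoms["name"] == "CA")
            & ~self.atoms["resname"].isin(WATER_RESNAMES)
            & ~self.atoms.index.isin(self.ligand_indices)
        )
        return self.atoms.index[mask].to_numpy()


#: selector roles: residue types they apply to and the PDB atom name(s) picked.
#: "ring_C4" is the para ring carbon of Phe/Tyr: counting from the attachment
#: carbon C1=CG, the fourth ring carbon is CZ.  "arg_CE" is the guanidinium
#: carbon CZ (arginine has no Cε in PDB nomenclature; CZ is the carbon probe
#: conventionally paired with Glu CD for the ionic lock).
ATOM_ROLES: dict[str, tuple[frozenset[str], tuple[str, ...]]] = {
    "CA": (frozenset(), ("CA",)),  # any residue type
    "ring_C4": (frozenset({"PHE", "TYR"}), ("CZ",)),
    "arg_CE": (frozenset({"ARG"}), ("CZ",)),
    "glu_CD": (frozenset({"GLU"}), ("CD",)),
    "tyr_OH": (frozenset({"TYR"}), ("OH",)),
    "carboxylate_O_pair": (frozenset({"ASP", "GLU"}), ()),
    "guanidinium_N_set": (frozenset({"ARG"}), ("NE", "NH1", "NH2")),
}

_CARBOXYLATE = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def select_atom(
    top: TopologyMap, bw: BWIndex | str, atom_role: str
) -> "int | tuple[int, ...]":
    """Deterministically select the atom(s) of ``bw`` playing ``atom_role``.

    Returns a single index for single-atom roles (CA, ring_C4, arg_CE,
    glu_CD, tyr_OH) and a tuple for set roles (carboxylate_O_pair,
    guanidinium_N_set).
    """
    if atom_role not in ATOM_ROLES:
        raise TopologyError(f"unknown atom role {atom_role!r}")
    bw = _as_bw(bw)
    sub = top.resolve_bw(bw)
    resname = str(sub["resname"].iloc[0])
    allowed, names = ATOM_ROLES[atom_role]
    if allowed and resname not in allowed:
        raise TopologyError(
            f"role {atom_role!r} not applicable to {resname} at {bw}"
        )
    if atom_role == "carboxylate_O_pair":
        names = _CARBOXYLATE[resname]
    picked = []
    for name in names:
        match = sub.index[sub["name"] == name]
        if len(match) == 0:
            raise TopologyError(f"atom {name} missing in {resname}{bw} for {atom_role}")
        picked.append(int(match[0]))
    if atom_role in ("carboxylate_O_pair", "guanidinium_N_set"):
        return tuple(picked)
    return picked[0]


@dataclass
class Trajectory:
    """In-memory trajectory: (n_frames, n_atoms, 3) coordinates in Å.

    Times are in ps and strictly increasing; ``box`` (optional) holds
    per-frame box dimensions in Å.
    """

    coords: np.ndarray
    times: np.ndarray
    box: "np.ndarray | None" = None
    replicate: "str | None" = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise TrajectoryError("trajectory must have at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("non-finite coordinates")
        if len(self.times) != self.coords.shape[0]:
            raise TrajectoryError("times length must equal n_frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _universe_from_top(top: TopologyMap):
    """Build a bare MDAnalysis Universe carrying this topology's attributes."""
    import MDAnalysis as mda

    atoms = top.atoms
    resseqs = atoms["resseq"].to_numpy()
    # contiguous residue blocks -> residue indices
    boundaries = np.r_[True, np.diff(resseqs) != 0]
    resindex = np.cumsum(boundaries) - 1
    n_res = int(resindex[-1]) + 1
    u = mda.Universe.empty(
        n_atoms=len(atoms),
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["name"].to_numpy())
    u.add_TopologyAttr("resids", resseqs[boundaries])
    u.add_TopologyAttr("resnames", atoms["resname"].to_numpy()[boundaries])
    u.add_TopologyAttr("elements", atoms["element"].to_numpy())
    return u


def load_topology(
    pdb_source: "str | Path",
    bw_table: "BWTable | str | Path",
    ligand_resnames: Iterable[str] = DEFAULT_LIGAND_RESNAMES,
    water_resnames: Iterable[str] = WATER_RESNAMES,
    receptor: str = "",
) -> TopologyMap:
    """Parse a PDB and couple it to a BW numbering table.

    Every BW entry in the table must resolve to at least one atom; a missing
    anchor residue is a hard error naming the offending BW index.  Ligand and
    water-oxygen atom sets are identified by residue-name rules.
    """
    import MDAnalysis as mda

    if not isinstance(bw_table, BWTable):
        bw_table = BWTable.from_tsv(bw_table, receptor=receptor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guessers are chatty on bare PDBs
        u = mda.Universe(str(pdb_source))
    names = [a.name for a in u.atoms]
    resnames = [a.resname for a in u.atoms]
    resseqs = [int(a.resid) for a in u.atoms]
    elements = [_guess_element(n) for n in names]
    atoms = pd.DataFrame(
        {"name": names, "resname": resnames, "resseq": resseqs, "element": elements}
    )
    ligand_set = frozenset(ligand_resnames)
    water_set = frozenset(water_resnames)
    ligand_idx = atoms.index[atoms["resname"].isin(ligand_set)].to_numpy()
    water_o = atoms.index[
        atoms["resname"].isin(water_set) & (atoms["element"] == "O")
    ].to_numpy()
    top = TopologyMap(
        atoms=atoms,
        bw=bw_table,
        ligand_indices=ligand_idx,
        water_oxygen_indices=water_o,
        source=str(pdb_source),
    )
    for bw, resseq, resname in bw_table.entries:
        sub = top.atoms_of_residue(resseq)
        if len(sub) == 0:
            raise TopologyError(
                f"BW anchor {bw} (residue {resseq}) missing from {pdb_source}"
            )
        if resname and str(sub["resname"].iloc[0]) != resname:
            raise TopologyError(
                f"BW anchor {bw}: expected {resname}{resseq}, "
                f"found {sub['resname'].iloc[0]}{resseq}"
            )
    return top


def read_trajectory(
    source: "str | Path | Sequence[str | Path]",
    top: TopologyMap,
    replicate: "str | None" = None,
) -> Trajectory:
    """Read DCD/XTC/multi-model-PDB coordinates against ``top``.

    Output is always Å / ps irrespective of the source format's native units
    (MDAnalysis converts XTC nm to Å).  Atom-count mismatch and non-monotonic
    times are hard errors.
    """
    u = _universe_from_top(top)
    try:
        u.load_new(str(source))
    except (OSError, ValueError) as exc:
        raise TrajectoryError(f"cannot read trajectory {source}: {exc}") from exc
    if u.atoms.n_atoms != top.n_atoms:
        raise TrajectoryError(
            f"atom count mismatch: trajectory has {u.atoms.n_atoms}, "
            f"topology has {top.n_atoms}"
        )
    coords, times, boxes = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # reader dt guesses and API chatter
        for ts in u.trajectory:
            coords.append(ts.positions.astype(float).copy())
            times.append(float(ts.time))
            boxes.append(None if ts.dimensions is None else ts.dimensions[:3].copy())
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        # some writers store zero times for every frame; fall back to indices
        if np.allclose(times_arr, times_arr[0]):
            times_arr = np.arange(len(times_arr), dtype=float)
        else:
            raise TrajectoryError("non-monotonic frame times")
    box = None
    if all(b is not None for b in boxes):
        box = np.asarray(boxes)
    return Trajectory(
        coords=np.asarray(coords), times=times_arr, box=box, replicate=replicate
    )


def write_trajectory(traj: Trajectory, path: "str | Path", top: TopologyMap) -> None:
    """Write a trajectory as DCD, XTC, or multi-model PDB (by extension)."""
    import MDAnalysis as mda

    u = _universe_from_top(top)
    u.load_new(traj.coords.astype(np.float32), format="memory", dt=1.0)
    path = str(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=top.n_atoms, multiframe=True) as w:
            for i, ts in enumerate(u.trajectory):
                ts.time = float(traj.times[i])
                if traj.box is not None:
                    ts.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def write_reference_pdb(coords: np.ndarray, path: "str | Path", top: TopologyMap) -> None:
    """Write a single-model PDB with this topology's atoms at ``coords``."""
    import MDAnalysis as mda

    u = _universe_from_top(top)
    u.load_new(np.asarray(coords, dtype=np.float32)[None, :, :], format="memory")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=top.n_atoms) as w:
            w.write(u.atoms)
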