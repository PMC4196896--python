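"""Synthetic trajectory generators with known ground truth.

Every input the analysis layer consumes can be generated here with its true
parameters returned alongside, so the whole pipeline is validated by
parameter recovery rather than by comparison to unavailable production
trajectories:

* two-state (engaged/disengaged) Markov switching distance dynamics with a
  prescribed stationary engaged fraction, dwell time and Gaussian noise;
* ideal α-helices and rigidly rotating helix trajectories (optionally with a
  global tumbling nuisance motion);
* uniformly solvated boxes at a prescribed water density, optionally with a
  water pinned near a marker atom in a prescribed fraction of frames;
* a 2D overdamped Langevin walker on an analytic potential with on-the-fly
  well-tempered hill deposition and a shared multiple-walker bias.

Ground-truth labels are drawn first and coordinates are built from them —
never the other way round — so recovery tests are not circular.  A single
global seed fans out into independent per-component streams, so adding a
generator does not perturb existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import GpcrSwitchError
from .helices import HelixSpan
from ._geom import random_rotation, rotation_matrix_about
from .metad import HillsLog
from .structure import BWIndex, BWTable, TopologyMap, Trajectory

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/mol/K


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Independent random stream for one generator component.

    The component name is hashed into the seed sequence's spawn key, so
    streams are stable under addition of new components.
    """
    key = zlib.crc32(component.encode())
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


# ---------------------------------------------------------------------------
# two-state switching dynamics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwitchSimSpec:
    """Two-state switching distance dynamics.

    The engaged/disengaged flag follows a stationary two-state Markov chain
    with engaged fraction ``p`` and relaxation (dwell) scale ``dwell``
    frames: per-frame transition probabilities are (1-p)/dwell out of the
    engaged state and p/dwell into it, giving autocorrelation
    (1 - 1/dwell)^k.  The distance is the state's mean plus iid Gaussian
    noise.  Means must straddle ``threshold`` by at least 3σ each
    (separability), so threshold classification recovers the chain.
    """

    p: float
    dwell: float = 50.0
    engaged_distance: float = 8.5
    disengaged_distance: float = 10.5
    noise_sigma: float = 0.25
    threshold: float = 9.5
    n_frames: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise GpcrSwitchError(f"stationary fraction must be in [0,1], got {self.p}")
        if self.dwell < 1:
            raise GpcrSwitchError("mean dwell must be >= 1 frame")
        lo, hi = sorted((self.engaged_distance, self.disengaged_distance))
        if not (
            lo + 3 * self.noise_sigma <= self.threshold
            and hi - 3 * self.noise_sigma >= self.threshold
        ):
            raise GpcrSwitchError(
                "state means must straddle the threshold by >= 3 sigma "
                f"({lo}, {hi}) vs {self.threshold} with sigma {self.noise_sigma}"
            )


#: ionic-lock flavour of the defaults: the 5 Å threshold with wider states
LOCK_SIM_DEFAULTS = dict(
    engaged_distance=3.5, disengaged_distance=7.0, noise_sigma=0.4, threshold=5.0
)


def markov_states(
    p: float, dwell: float, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Stationary two-state chain sample: True = engaged."""
    if p in (0.0, 1.0):
        return np.full(n_frames, bool(p))
    q_out = (1.0 - p) / dwell  # engaged -> disengaged
    q_in = p / dwell  # disengaged -> engaged
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=bool)
    states[0] = u[0] < p
    for t in range(1, n_frames):
        if states[t - 1]:
            states[t] = u[t] >= q_out
        else:
            states[t] = u[t] < q_in
    return states


def expected_transitions(p: float, dwell: float, n_frames: int) -> float:
    """Expected number of consecutive-frame flips of the stationary chain."""
    return (n_frames - 1) * 2.0 * p * (1.0 - p) / dwell


def engagement_ci_halfwidth(
    p: float, n_frames: int, dwell: float, level: float = 0.99
) -> float:
    """CI half-width for the engaged-fraction estimate of the Markov chain.

    The chain's autocorrelation is geometric with ratio λ = 1 - 1/dwell, so
    the variance of the mean indicator inflates the binomial variance by the
    integrated autocorrelation factor (1+λ)/(1-λ) = 2·dwell - 1.
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    var = p * (1.0 - p) / n_frames * (2.0 * dwell - 1.0)
    return float(z * np.sqrt(var))


def gen_switch_distances(
    spec: SwitchSimSpec, rng: "np.random.Generator | None" = None
) -> tuple[np.ndarray, np.ndarray]:
    """(distances, true states) for one switching spec."""
    if rng is None:
        rng = component_rng(spec.seed, "switch_distances")
    states = markov_states(spec.p, spec.dwell, spec.n_frames, rng)
    means = np.where(states, spec.engaged_distance, spec.disengaged_distance)
    distances = means + spec.noise_sigma * rng.normal(size=spec.n_frames)
    return np.clip(distances, 0.05, None), states


def gen_switch_trajectory(
    spec: SwitchSimSpec,
) -> tuple[Trajectory, TopologyMap, np.ndarray]:
    """Minimal two-marker-atom trajectory realizing one switching spec.

    Atom 0 sits at the origin; atom 1 sits at (d(t), 0, 0).  Returns the
    trajectory, its two-atom topology and the true state labels.
    """
    distances, states = gen_switch_distances(spec)
    coords = np.zeros((spec.n_frames, 2, 3))
    coords[:, 1, 0] = distances
    atoms = pd.DataFrame(
        {
            "name": ["CA", "CA"],
            "resname": ["ALA", "ALA"],
            "resseq": [1, 2],
            "element": ["C", "C"],
        }
    )
    bw = BWTable(((BWIndex(1, 50), 1, "ALA"),))
    top = TopologyMap(atoms=atoms, bw=bw, source="synthetic:switch")
    traj = Trajectory(
        coords=coords, times=np.arange(spec.n_frames, dtype=float), replicate="synth"
    )
    return traj, top, states


# ---------------------------------------------------------------------------
# marker-receptor bundle covering every built-in switch
# ---------------------------------------------------------------------------

_MARKER_RESIDUES: tuple[tuple[int, str, tuple[str, ...]], ...] = (
    (149, "ASP", ("OD1", "OD2")),
    (150, "ARG", ("CA", "CZ", "NE", "NH1", "NH2")),
    (240, "ALA", ("CA",)),
    (250, "ALA", ("CA",)),
    (254, "ALA", ("CA",)),
    (330, "GLU", ("CD",)),
    (341, "PHE", ("CZ",)),
    (344, "PHE", ("CZ",)),
    (353, "TYR", ("OH",)),
)

_MARKER_BW_ENTRIES: tuple[tuple[str, int, str], ...] = (
    ("3.49", 149, "ASP"),
    ("3.50", 150, "ARG"),
    ("2.40", 240, "ALA"),
    ("5.50", 250, "ALA"),
    ("5.54", 254, "ALA"),
    ("6.30", 330, "GLU"),
    ("6.41", 341, "PHE"),
    ("6.44", 344, "PHE"),
    ("7.53", 353, "TYR"),
)

#: default engaged fractions used by the marker bundle, one per classified
#: switch (configurable per call)
DEFAULT_BUNDLE_P = {
    "F6.44_activation": 0.54,
    "F6.41_activation": 0.54,
    "ionic_lock": 0.14,
    "D3.49-R3.50_salt_bridge": 0.38,
}


def marker_topology(receptor: str = "synthetic") -> TopologyMap:
    """Marker 'receptor' whose residues cover every built-in switch selector."""
    rows = []
    for resseq, resname, names in _MARKER_RESIDUES:
        for name in names:
            element = "O" if name.startswith("O") else ("N" if name.startswith("N") else "C")
            rows.append((name, resname, resseq, element))
    atoms = pd.DataFrame(rows, columns=["name", "resname", "resseq", "element"])
    bw = BWTable(
        tuple((BWIndex.parse(b), r, n) for b, r, n in _MARKER_BW_ENTRIES),
        receptor=receptor,
    )
    return TopologyMap(atoms=atoms, bw=bw, source="synthetic:marker")


def _atom_index(top: TopologyMap, resseq: int, name: str) -> int:
    sub = top.atoms[(top.atoms["resseq"] == resseq) & (top.atoms["name"] == name)]
    return int(sub.index[0])


def gen_switch_bundle(
    p_by_switch: "dict[str, float] | None" = None,
    n_frames: int = 10_000,
    dwell: float = 50.0,
    seed: int = 0,
    replicate: str = "rep0",
) -> tuple[Trajectory, TopologyMap, dict[str, np.ndarray]]:
    """Marker trajectory in which every built-in switch follows its own chain.

    Each switch's moving atom is displaced along +x from its static partner
    at a well-separated base position; chains are driven by independent
    streams derived from ``seed`` and ``replicate``.  Returns the trajectory,
    topology and the true state labels per switch.
    """
    p_map = dict(DEFAULT_BUNDLE_P)
    if p_by_switch:
        unknown = set(p_by_switch) - set(p_map)
        if unknown:
            raise GpcrSwitchError(f"unknown switch names {sorted(unknown)}")
        p_map.update(p_by_switch)
    top = marker_topology()
    coords = np.zeros((n_frames, top.n_atoms, 3))
    truth: dict[str, np.ndarray] = {}

    def place(static: list[tuple[int, str]], moving: list[tuple[int, str]],
              base_y: float, distances: np.ndarray) -> None:
        for resseq, name in static:
            coords[:, _atom_index(top, resseq, name), 1] = base_y
        for resseq, name in moving:
            i = _atom_index(top, resseq, name)
            coords[:, i, 0] = distances
            coords[:, i, 1] = base_y

    specs = {
        "F6.44_activation": SwitchSimSpec(
            p=p_map["F6.44_activation"], dwell=dwell, n_frames=n_frames
        ),
        "F6.41_activation": SwitchSimSpec(
            p=p_map["F6.41_activation"], dwell=dwell, n_frames=n_frames
        ),
        "ionic_lock": SwitchSimSpec(
            p=p_map["ionic_lock"], dwell=dwell, n_frames=n_frames, **LOCK_SIM_DEFAULTS
        ),
        "D3.49-R3.50_salt_bridge": SwitchSimSpec(
            p=p_map["D3.49-R3.50_salt_bridge"],
            dwell=dwell,
            n_frames=n_frames,
            engaged_distance=3.0,
            disengaged_distance=6.0,
            noise_sigma=0.3,
            threshold=4.0,
        ),
    }
    layout = {
        "F6.44_activation": ([(250, "CA")], [(344, "CZ")], 0.0),
        "F6.41_activation": ([(254, "CA")], [(341, "CZ")], 50.0),
        "ionic_lock": ([(330, "CD")], [(150, "CZ")], 100.0),
        "D3.49-R3.50_salt_bridge": (
            [(149, "OD1"), (149, "OD2")],
            [(150, "NE"), (150, "NH1"), (150, "NH2")],
            150.0,
        ),
    }
    for name, spec in specs.items():
        rng = component_rng(seed, f"bundle:{replicate}:{name}")
        distances, states = gen_switch_distances(spec, rng)
        static, moving, base_y = layout[name]
        place(static, moving, base_y, distances)
        truth[name] = states
    # static Y7.53 reporter geometry: OH at y=200, partners at 7 and 10 A
    coords[:, _atom_index(top, 353, "OH"), 1] = 200.0
    coords[:, _atom_index(top, 150, "CA"), :2] = (7.0, 200.0)
    coords[:, _atom_index(top, 240, "CA"), :2] = (0.0, 210.0)
    traj = Trajectory(
        coords=coords, times=np.arange(n_frames, dtype=float), replicate=replicate
    )
    return traj, top, truth


# ---------------------------------------------------------------------------
# helices
# ---------------------------------------------------------------------------


def gen_helix(
    n_res: int, rise: float = 1.5, twist: float = 100.0, radius: float = 2.3
) -> np.ndarray:
    """Ideal α-helix Cα trace along +z (rise Å/residue, twist °/residue)."""
    if n_res < 4:
        raise GpcrSwitchError("need >= 4 residues")
    i = np.arange(n_res)
    ang = np.deg2rad(twist) * i
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), rise * i], axis=1)


def gen_rotating_helix_traj(
    angles_deg: np.ndarray,
    n_res: int = 17,
    global_tumbling: bool = False,
    seed: int = 0,
) -> tuple[Trajectory, TopologyMap, HelixSpan, np.ndarray]:
    """Trajectory of a rigid helix rotated about its own axis per frame.

    The system holds a static 'core' helix (for rigid-body pre-alignment)
    displaced 15 Å in x, plus the measured span rotated by the requested
    angle each frame.  With ``global_tumbling`` a random rigid rotation and
    translation is applied to all atoms per frame, which pre-alignment on the
    core must remove.  Returns (trajectory, topology, span, true angles); the
    reference structure is the unrotated construction (frame of angle 0).
    """
    angles = np.asarray(angles_deg, dtype=float)
    span_xyz = gen_helix(n_res)
    core_xyz = gen_helix(24) + np.array([15.0, 0.0, 0.0])
    n_core = len(core_xyz)
    axis = np.array([0.0, 0.0, 1.0])
    centroid = span_xyz.mean(axis=0)
    rng = component_rng(seed, "rotating_helix")
    n_frames = len(angles)
    coords = np.empty((n_frames, n_core + n_res, 3))
    for f, theta in enumerate(angles):
        R = rotation_matrix_about(axis, theta)
        rotated = (span_xyz - centroid) @ R.T + centroid
        frame = np.vstack([core_xyz, rotated])
        if global_tumbling:
            Rg = random_rotation(rng)
            tg = rng.uniform(-20.0, 20.0, size=3)
            frame = frame @ Rg.T + tg
        coords[f] = frame
    rows = []
    for k in range(n_core):
        rows.append(("CA", "ALA", 100 + k, "C"))
    span_start = 44
    for k in range(n_res):
        rows.append(("CA", "ALA", 644 + k, "C"))
    atoms = pd.DataFrame(rows, columns=["name", "resname", "resseq", "element"])
    bw_entries = [(BWIndex(1, 50), 100 + 10, "ALA")] + [
        (BWIndex(6, span_start + k), 644 + k, "ALA") for k in range(n_res)
    ]
    top = TopologyMap(atoms=atoms, bw=BWTable(tuple(bw_entries)),
                      source="synthetic:rotating_helix")
    span = HelixSpan(
        start=BWIndex(6, span_start),
        end=BWIndex(6, span_start + n_res - 1),
        ca_indices=np.arange(n_core, n_core + n_res),
    )
    traj = Trajectory(coords=coords, times=np.arange(n_frames, dtype=float))
    return traj, top, span, angles


# ---------------------------------------------------------------------------
# solvated boxes
# ---------------------------------------------------------------------------


def gen_solvated_box(
    density: float = 0.0334,
    box: tuple[float, float, float] = (20.0, 20.0, 20.0),
    n_frames: int = 100,
    seed: int = 0,
    pinned_fraction: float = 0.0,
    pinned_cutoff: float = 2.0,
) -> tuple[Trajectory, TopologyMap, np.ndarray]:
    """Uniform iid water-oxygen placements per frame at the given density.

    A marker Cα atom sits at the box center.  When ``pinned_fraction`` > 0,
    its integer part gives the number of waters held inside ``pinned_cutoff``
    of the marker in every frame and its fractional part the Bernoulli
    probability that one further water is pinned (so a value of 1.4 yields a
    mean near-marker count of 1.4); all other waters are excluded from the
    marker sphere so the near-marker count is exactly the pinned count.
    Returns (trajectory, topology, true pinned count per frame).
    """
    if density < 0:
        raise GpcrSwitchError("density must be >= 0")
    rng = component_rng(seed, "solvated_box")
    box_arr = np.asarray(box, dtype=float)
    n_waters = int(round(density * np.prod(box_arr)))
    center = box_arr / 2.0
    n_atoms = 1 + n_waters
    coords = np.empty((n_frames, n_atoms, 3))
    coords[:, 0, :] = center
    n_always = int(pinned_fraction)
    frac = pinned_fraction - n_always
    if n_always + (frac > 0) > n_waters:
        raise GpcrSwitchError("pinned_fraction exceeds the available waters")
    pinned = np.zeros(n_frames, dtype=int)
    exclude = pinned_fraction > 0.0
    if n_waters > 0:
        pts = rng.uniform(0.0, 1.0, size=(n_frames, n_waters, 3)) * box_arr
        if exclude:
            # resample any water that landed inside the marker sphere
            for f in range(n_frames):
                d = np.linalg.norm(pts[f] - center, axis=1)
                while np.any(d <= pinned_cutoff):
                    bad = d <= pinned_cutoff
                    pts[f, bad] = rng.uniform(0.0, 1.0, size=(bad.sum(), 3)) * box_arr
                    d[bad] = np.linalg.norm(pts[f, bad] - center, axis=1)
        coords[:, 1:, :] = pts

    def _in_sphere():
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        return center + 0.9 * pinned_cutoff * rng.random() ** (1.0 / 3.0) * v

    if exclude and n_waters > 0:
        pinned += n_always
        for w in range(n_always):
            for f in range(n_frames):
                coords[f, 1 + w, :] = _in_sphere()
        if frac > 0:
            bern = rng.random(n_frames) < frac
            pinned += bern.astype(int)
            for f in np.nonzero(bern)[0]:
                coords[f, 1 + n_always, :] = _in_sphere()
    rows = [("CA", "ALA", 1, "C")] + [("O", "HOH", 2 + k, "O") for k in range(n_waters)]
    atoms = pd.DataFrame(rows, columns=["name", "resname", "resseq", "element"])
    bw = BWTable(((BWIndex(5, 36), 1, "ALA"),))
    top = TopologyMap(
        atoms=atoms,
        bw=bw,
        water_oxygen_indices=np.arange(1, n_atoms),
        source="synthetic:solvated_box",
    )
    traj = Trajectory(
        coords=coords,
        times=np.arange(n_frames, dtype=float),
        box=np.tile(box_arr, (n_frames, 1)),
    )
    return traj, top, pinned


# ---------------------------------------------------------------------------
# overdamped Langevin walker with well-tempered hill deposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoubleWell2D:
    """Quartic double well along cv1 plus a harmonic channel along cv2.

    U = barrier · ((Δx² - a²)² / a⁴) + ½ k_perp Δy², with minima at
    center ± (a, 0) and a saddle of height ``barrier`` at the center.
    """

    barrier: float = 1.5  # kcal/mol
    center: tuple[float, float] = (9.5, 9.5)  # Å
    half_separation: float = 1.0  # Å
    k_perp: float = 2.0  # kcal/mol/Å²

    @property
    def minima(self) -> tuple[tuple[float, float], tuple[float, float]]:
        cx, cy = self.center
        a = self.half_separation
        return ((cx - a, cy), (cx + a, cy))

    def value(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        dx = pts[..., 0] - self.center[0]
        dy = pts[..., 1] - self.center[1]
        a2 = self.half_separation**2
        return self.barrier * (dx**2 - a2) ** 2 / a2**2 + 0.5 * self.k_perp * dy**2

    def grad(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        dx = pts[..., 0] - self.center[0]
        dy = pts[..., 1] - self.center[1]
        a2 = self.half_separation**2
        gx = self.barrier * 4.0 * dx * (dx**2 - a2) / a2**2
        gy = self.k_perp * dy
        return np.stack([gx, gy], axis=-1)


@dataclass(frozen=True)
class Harmonic2D:
    """Isotropic-by-axis harmonic well U = ½ kx Δx² + ½ ky Δy²."""

    k: tuple[float, float] = (1.0, 1.0)
    center: tuple[float, float] = (9.5, 9.5)

    def value(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        dx = pts[..., 0] - self.center[0]
        dy = pts[..., 1] - self.center[1]
        return 0.5 * self.k[0] * dx**2 + 0.5 * self.k[1] * dy**2

    def grad(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        dx = pts[..., 0] - self.center[0]
        dy = pts[..., 1] - self.center[1]
        return np.stack([self.k[0] * dx, self.k[1] * dy], axis=-1)


@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped Langevin walkers with shared well-tempered bias.

    Defaults mirror the production metadynamics parameters where stated:
    hill height 0.1 kcal/mol, widths 0.1 Å per CV, one hill every 4 ps,
    bias factor 10, six walkers sharing the bias with a 20 ps exchange
    interval, at 300 K.  Diffusion coefficient and timestep are toy-model
    scales chosen for stability of the stiffest mode.
    """

    potential: object = field(default_factory=DoubleWell2D)
    temperature: float = 300.0  # K
    diffusion: float = 0.05  # Å²/ps
    timestep: float = 0.05  # ps
    n_steps: int = 100_000  # per walker
    n_walkers: int = 6
    hill_height: float = 0.1  # kcal/mol, nominal (before tempering)
    hill_sigma: tuple[float, float] = (0.1, 0.1)  # Å
    pace_ps: float = 4.0  # hill deposition period
    exchange_ps: float = 20.0  # multiple-walker bias refresh period
    gamma: float = 10.0  # well-tempered bias factor
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((6.0, 13.0), (6.0, 13.0))
    bias_grid_spacing: float = 0.05  # Å, internal bias accumulation grid
    save_stride: int = 10

    def __post_init__(self) -> None:
        if self.pace_ps < self.timestep and self.hill_height > 0:
            raise GpcrSwitchError("pace must be >= one timestep")
        if self.gamma <= 1:
            raise GpcrSwitchError("well-tempered bias factor must exceed 1")


@dataclass
class LangevinResult:
    """CV trajectories (n_walkers, n_saved, 2), hills log and times."""

    cv_traj: np.ndarray
    times: np.ndarray
    hills: HillsLog
    spec: LangevinSpec


class _WalkerBias:
    """Shared + per-walker-pending bias on a regular grid.

    Hills are deposited as Gaussian patches (±5σ support) into a walker's
    pending layer; an exchange flushes all pending layers into the shared
    layer.  Each walker's effective bias is shared + its own pending, and the
    potential and its analytic gradient are bilinearly interpolated at the
    walker positions in one vectorized pass.
    """

    def __init__(self, bounds, spacing, n_walkers):
        (x0, x1), (y0, y1) = bounds
        self.x0, self.y0, self.h = x0, y0, spacing
        self.nx = int(np.floor((x1 - x0) / spacing)) + 1
        self.ny = int(np.floor((y1 - y0) / spacing)) + 1
        # channel 0: V, 1: dV/dx, 2: dV/dy
        self.shared = np.zeros((3, self.nx, self.ny))
        self.pending = np.zeros((n_walkers, 3, self.nx, self.ny))

    def deposit(self, walker, cx, cy, sx, sy, w):
        rx = max(1, int(np.ceil(5 * sx / self.h)))
        ry = max(1, int(np.ceil(5 * sy / self.h)))
        ci = int(round((cx - self.x0) / self.h))
        cj = int(round((cy - self.y0) / self.h))
        i0, i1 = max(0, ci - rx), min(self.nx, ci + rx + 1)
        j0, j1 = max(0, cj - ry), min(self.ny, cj + ry + 1)
        xs = self.x0 + self.h * np.arange(i0, i1)
        ys = self.y0 + self.h * np.arange(j0, j1)
        ex = np.exp(-((xs - cx) ** 2) / (2 * sx**2))
        ey = np.exp(-((ys - cy) ** 2) / (2 * sy**2))
        g = w * ex[:, None] * ey[None, :]
        self.pending[walker, 0, i0:i1, j0:j1] += g
        self.pending[walker, 1, i0:i1, j0:j1] += g * (-(xs - cx) / sx**2)[:, None]
        self.pending[walker, 2, i0:i1, j0:j1] += g * (-(ys - cy) / sy**2)[None, :]

    def exchange(self):
        self.shared += self.pending.sum(axis=0)
        self.pending[:] = 0.0

    def interp(self, pos):
        """(V, gradV) of each walker's effective bias at its own position."""
        nw = len(pos)
        gx = np.clip((pos[:, 0] - self.x0) / self.h, 0, self.nx - 1.000001)
        gy = np.clip((pos[:, 1] - self.y0) / self.h, 0, self.ny - 1.000001)
        i = gx.astype(int)
        j = gy.astype(int)
        fx = (gx - i)[None, :]
        fy = (gy - j)[None, :]
        w_idx = np.arange(nw)

        def corner(di, dj):
            return self.shared[:, i + di, j + dj] + self.pending[
                w_idx, :, i + di, j + dj
            ].T

        out = (
            corner(0, 0) * (1 - fx) * (1 - fy)
            + corner(1, 0) * fx * (1 - fy)
            + corner(0, 1) * (1 - fx) * fy
            + corner(1, 1) * fx * fy
        )  # (3, nw)
        return out[0], out[1:].T


def run_langevin_metad(spec: LangevinSpec, seed: int = 0) -> LangevinResult:
    """Simulate the multiple-walker biased Langevin system.

    Walkers follow overdamped dynamics on (analytic potential + bias); each
    deposits a hill every ``pace_ps`` with the well-tempered height
    w = h0·exp(-V(s)/(kB·ΔT)), evaluated on its current bias view.  Newly
    deposited hills become visible to the other walkers at the exchange
    interval (each walker always sees its own pending hills).  Walkers are
    reflected at the CV bounds.
    """
    rng = component_rng(seed, "langevin_metad")
    pot = spec.potential
    kT = KB_KCAL * spec.temperature
    dT = (spec.gamma - 1.0) * spec.temperature
    kB_dT = KB_KCAL * dT
    dt = spec.timestep
    mobility = spec.diffusion / kT
    noise_scale = np.sqrt(2.0 * spec.diffusion * dt)
    nw = spec.n_walkers
    (x0, x1), (y0, y1) = spec.bounds

    bias = _WalkerBias(spec.bounds, spec.bias_grid_spacing, nw)

    # walkers start spread over the potential minima (or center)
    if hasattr(pot, "minima"):
        starts = np.array(pot.minima)
        pos = starts[np.arange(nw) % len(starts)].astype(float).copy()
    else:
        pos = np.tile(np.asarray(pot.center, dtype=float), (nw, 1))
    pos += 0.05 * rng.normal(size=(nw, 2))

    pace_steps = max(1, int(round(spec.pace_ps / dt)))
    exchange_steps = max(1, int(round(spec.exchange_ps / dt)))
    deposit = spec.hill_height > 0

    n_saved = spec.n_steps // spec.save_stride
    cv_traj = np.empty((nw, n_saved, 2))
    saved_times = np.empty(n_saved)
    hill_rows: list[tuple] = []

    noise = rng.normal(size=(spec.n_steps, nw, 2))
    for step in range(spec.n_steps):
        force = -pot.grad(pos)
        if deposit:
            _, bias_grad = bias.interp(pos)
            force -= bias_grad
        pos = pos + mobility * force * dt + noise_scale * noise[step]
        # reflecting boundaries
        pos[:, 0] = np.where(pos[:, 0] < x0, 2 * x0 - pos[:, 0], pos[:, 0])
        pos[:, 0] = np.where(pos[:, 0] > x1, 2 * x1 - pos[:, 0], pos[:, 0])
        pos[:, 1] = np.where(pos[:, 1] < y0, 2 * y0 - pos[:, 1], pos[:, 1])
        pos[:, 1] = np.where(pos[:, 1] > y1, 2 * y1 - pos[:, 1], pos[:, 1])

        if deposit and (step + 1) % pace_steps == 0:
            t_ps = (step + 1) * dt
            v_here, _ = bias.interp(pos)
            sx, sy = spec.hill_sigma
            for w in range(nw):
                height = spec.hill_height * np.exp(-float(v_here[w]) / kB_dT)
                bias.deposit(w, pos[w, 0], pos[w, 1], sx, sy, height)
                hill_rows.append(
                    (t_ps, pos[w, 0], pos[w, 1], sx, sy, height, spec.gamma, w)
                )
        if deposit and (step + 1) % exchange_steps == 0:
            bias.exchange()

        if (step + 1) % spec.save_stride == 0:
            k = (step + 1) // spec.save_stride - 1
            cv_traj[:, k, :] = pos
            saved_times[k] = (step + 1) * dt

    records = pd.DataFrame(
        hill_rows,
        columns=[
            "time_ps", "cv1", "cv2", "sigma1", "sigma2", "height",
            "biasfactor", "walker",
        ],
    )
    records = records.sort_values(
        ["time_ps", "walker"], kind="stable", ignore_index=True
    )
    hills = HillsLog(
        records=records, gamma=spec.gamma, temperature=spec.temperature
    )
    return LangevinResult(cv_traj=cv_traj, times=saved_times, hills=hills, spec=spec)


# ---------------------------------------------------------------------------
# on-disk fixture bundle
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    outdir: "str | Path",
    seed: int = 0,
    n_frames: int = 2000,
    n_replicates: int = 2,
    dwell: float = 50.0,
    p_by_switch: "dict[str, float] | None" = None,
) -> dict:
    """Write a complete on-disk input bundle in the formats the readers consume.

    Produces ``topology.pdb`` (reference structure), ``bw_table.tsv``, one
    multi-model PDB trajectory per replicate and ``manifest.json`` recording
    the ground-truth parameters.  Returns the manifest dict.
    """
    from .structure import write_reference_pdb, write_trajectory

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "n_frames": n_frames,
        "dwell": dwell,
        "replicates": [],
        "p_by_switch": dict(DEFAULT_BUNDLE_P, **(p_by_switch or {})),
    }
    top = None
    for r in range(n_replicates):
        rep = f"rep{r}"
        traj, top, truth = gen_switch_bundle(
            p_by_switch=p_by_switch,
            n_frames=n_frames,
            dwell=dwell,
            seed=seed,
            replicate=rep,
        )
        path = outdir / f"traj_{rep}.pdb"
        write_trajectory(traj, path, top)
        manifest["replicates"].append(
            {
                "file": path.name,
                "replicate": rep,
                "true_engaged_fraction": {
                    k: float(np.mean(v)) for k, v in truth.items()
                },
            }
        )
        if r == 0:
            write_reference_pdb(traj.coords[0], outdir / "topology.pdb", top)
    assert top is not None
    top.bw.to_tsv(outdir / "bw_table.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
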