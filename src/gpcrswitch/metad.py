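"""Well-tempered multiple-walker metadynamics: hills parsing and FES recovery.

In well-tempered metadynamics, Gaussian hills of geometrically decaying
height are deposited along two collective variables (here the two
micro-switch distances d1 = C-4 of F6.44 to Cα 5.50 and d2 = C-4 of F6.41 to
Cα 5.54).  The bias potential at any CV point is the plain sum of the
recorded Gaussians,

    V(s) = Σ_i w_i · exp( -Σ_k (s_k - s_{k,i})² / (2 σ_k²) ),

where the logged heights w_i are assumed to be the already-tempered values as
deposited (the convention of common metadynamics plugins; a switch supports
logs storing nominal heights instead).  The free-energy estimate is

    F(s) = -(γ / (γ - 1)) · V(s),          γ = (T + ΔT) / T,

shifted so its minimum is 0; with the study's bias factor γ = 10 the
prefactor is 10/9.  Multiple walkers contribute hills to the same bias; their
logs are merged and time-sorted before reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GpcrSwitchError, HillsParseError
from .structure import TopologyMap
from .switches import AtomSel, distance_series
from .structure import Trajectory

#: activation threshold on each CV distance (Å): ≤ 9.5 Å is the active side
ACTIVATION_THRESHOLD = 9.5

#: the two collective variables of the study
CV_DEFINITIONS: tuple[tuple[AtomSel, AtomSel], tuple[AtomSel, AtomSel]] = (
    (AtomSel("6.44", "ring_C4"), AtomSel("5.50", "CA")),
    (AtomSel("6.41", "ring_C4"), AtomSel("5.54", "CA")),
)

_HILLS_COLUMNS = ["time_ps", "cv1", "cv2", "sigma1", "sigma2", "height", "biasfactor"]


@dataclass
class HillsLog:
    """Merged record of deposited hills from one or more walkers.

    ``records`` columns: time_ps, cv1, cv2, sigma1, sigma2 (Å), height
    (kcal/mol, already-tempered as deposited), walker (int).
    """

    records: pd.DataFrame
    gamma: float
    temperature: float = 300.0
    tempered_heights: bool = True

    def __post_init__(self) -> None:
        r = self.records
        if len(r) > 0:
            if (r[["sigma1", "sigma2"]] <= 0).any().any():
                raise HillsParseError("hill widths must be > 0")
            if (r["height"] <= 0).any():
                raise HillsParseError("hill heights must be > 0")
            if not r["time_ps"].is_monotonic_increasing:
                raise HillsParseError("merged hills must be time-sorted")
        if self.gamma is not None and self.gamma <= 1:
            raise GpcrSwitchError(f"bias factor must exceed 1, got {self.gamma}")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def concat(cls, logs: "Sequence[HillsLog]") -> "HillsLog":
        if not logs:
            raise GpcrSwitchError("cannot concatenate zero hills logs")
        df = pd.concat([l.records for l in logs], ignore_index=True)
        df = df.sort_values(["time_ps", "walker"], kind="stable", ignore_index=True)
        return cls(df, gamma=logs[0].gamma, temperature=logs[0].temperature)


def _parse_hills_file(path: "str | Path", walker: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 6:
                raise HillsParseError(
                    f"{path}:{lineno}: expected >= 6 columns "
                    "(time cv1 cv2 sigma1 sigma2 height [biasfactor]), "
                    f"got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts[:7]]
            except ValueError as exc:
                raise HillsParseError(f"{path}:{lineno}: non-numeric field") from exc
            if len(vals) < 7:
                vals.append(np.nan)
            rows.append(vals)
    df = pd.DataFrame(rows, columns=_HILLS_COLUMNS)
    df["walker"] = walker
    return df


def read_hills(
    paths: "str | Path | Sequence[str | Path]",
    gamma: "float | None" = None,
    temperature: float = 300.0,
) -> HillsLog:
    """Read and merge HILLS-style text files, one per walker.

    Lines beginning with ``#`` (including ``#!`` headers) are ignored.
    Records from all walkers are merged and sorted by time, ties broken by
    ascending walker id.  ``gamma`` may be omitted when the files carry a
    biasfactor column.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = [_parse_hills_file(p, walker=i) for i, p in enumerate(paths)]
    df = pd.concat(frames, ignore_index=True)
    if gamma is None:
        declared = df["biasfactor"].dropna().unique()
        if len(declared) == 0:
            raise GpcrSwitchError(
                "bias factor not given and not present in hills files"
            )
        if len(declared) > 1:
            raise HillsParseError(f"inconsistent bias factors in files: {declared}")
        gamma = float(declared[0])
    df = df.sort_values(["time_ps", "walker"], kind="stable", ignore_index=True)
    return HillsLog(records=df, gamma=gamma, temperature=temperature)


def write_hills(log: HillsLog, path: "str | Path", walker: "int | None" = None) -> None:
    """Write a hills log (optionally one walker's records) as HILLS text."""
    df = log.records
    if walker is not None:
        df = df[df["walker"] == walker]
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf\n")
        for row in df.itertuples():
            bf = log.gamma if np.isnan(row.biasfactor) else row.biasfactor
            fh.write(
                f"{row.time_ps:.3f} {row.cv1:.6f} {row.cv2:.6f} "
                f"{row.sigma1:.6f} {row.sigma2:.6f} {row.height:.9f} {bf:.1f}\n"
            )


def bias_potential(log: HillsLog, points: np.ndarray) -> np.ndarray:
    """Sum of recorded Gaussian hills evaluated at CV points (..., 2)."""
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = np.zeros(len(pts))
    if len(log) == 0:
        return out[0] if scalar else out.reshape(np.asarray(points).shape[:-1])
    r = log.records
    c1 = r["cv1"].to_numpy()
    c2 = r["cv2"].to_numpy()
    s1 = r["sigma1"].to_numpy()
    s2 = r["sigma2"].to_numpy()
    w = r["height"].to_numpy()
    # chunk over hills to bound memory
    for lo in range(0, len(r), 4096):
        hi = lo + 4096
        e = (
            (pts[:, 0:1] - c1[None, lo:hi]) ** 2 / (2 * s1[None, lo:hi] ** 2)
            + (pts[:, 1:2] - c2[None, lo:hi]) ** 2 / (2 * s2[None, lo:hi] ** 2)
        )
        out += np.exp(-e) @ w[lo:hi]
    shape = np.asarray(points).shape[:-1]
    return out[0] if scalar else out.reshape(shape)


@dataclass
class FESGrid:
    """2D free-energy surface over regular CV axes, min-referenced to 0."""

    cv1_axis: np.ndarray
    cv2_axis: np.ndarray
    values: np.ndarray  # (n1, n2), kcal/mol
    gamma: float
    referenced: bool = True

    def reference(self) -> "FESGrid":
        return FESGrid(
            self.cv1_axis,
            self.cv2_axis,
            self.values - self.values.min(),
            self.gamma,
            referenced=True,
        )

    def to_gnuplot(self, path: "str | Path") -> None:
        """3-column text (cv1 cv2 F) with a blank line between cv1 blocks."""
        with open(path, "w") as fh:
            fh.write("# cv1_A cv2_A free_energy_kcal_mol\n")
            for i, x in enumerate(self.cv1_axis):
                for j, y in enumerate(self.cv2_axis):
                    fh.write(f"{x:.4f} {y:.4f} {self.values[i, j]:.6f}\n")
                fh.write("\n")

    def to_frame(self) -> pd.DataFrame:
        X, Y = np.meshgrid(self.cv1_axis, self.cv2_axis, indexing="ij")
        return pd.DataFrame(
            {
                "cv1_A": X.ravel(),
                "cv2_A": Y.ravel(),
                "free_energy_kcal_mol": self.values.ravel(),
            }
        )


def reconstruct_fes(
    log: HillsLog,
    cv1_axis: "np.ndarray | None" = None,
    cv2_axis: "np.ndarray | None" = None,
    reference: bool = True,
) -> FESGrid:
    """Well-tempered FES estimate F = -(γ/(γ-1))·V on a regular CV grid.

    Defaults to 120×120 nodes over [6, 14] Å × [6, 14] Å, which covers the
    crystal point and both activation states with the 0.1 Å hill width well
    resolved.  With ``reference=True`` the surface is shifted to min 0.
    """
    if log.gamma is None or log.gamma <= 1:
        raise GpcrSwitchError("well-tempered reconstruction requires gamma > 1")
    if cv1_axis is None:
        cv1_axis = np.linspace(6.0, 14.0, 120)
    if cv2_axis is None:
        cv2_axis = np.linspace(6.0, 14.0, 120)
    X, Y = np.meshgrid(cv1_axis, cv2_axis, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
    V = bias_potential(log, pts).reshape(X.shape)
    prefactor = log.gamma / (log.gamma - 1.0)
    if not log.tempered_heights:
        # nominal-height logs: the accumulated bias overestimates by γ/(γ-1)
        # relative to tempered deposition only in the long-time limit; for
        # such logs the estimator uses the bias as-is without the prefactor
        # correction being re-applied twice.
        prefactor = 1.0
    F = -prefactor * V
    grid = FESGrid(np.asarray(cv1_axis), np.asarray(cv2_axis), F, log.gamma,
                   referenced=False)
    return grid.reference() if reference else grid


@dataclass(frozen=True)
class StateRegion:
    """A rectangular CV region delimited by the activation threshold."""

    name: str
    cv1_active: bool  # True: d1 <= threshold side
    cv2_active: bool


#: the three mechanistic regions plus the quadrant the pathway avoids
STATE_REGIONS: tuple[StateRegion, ...] = (
    StateRegion("inactive", cv1_active=False, cv2_active=False),
    StateRegion("intermediate", cv1_active=False, cv2_active=True),
    StateRegion("active", cv1_active=True, cv2_active=True),
    StateRegion("forbidden_path", cv1_active=True, cv2_active=False),
)


def label_states(
    fes: FESGrid, threshold: float = ACTIVATION_THRESHOLD
) -> dict[str, dict]:
    """Minimum free energy and its location within each activation region.

    Regions partition the CV plane by the 9.5 Å threshold on each distance
    (the threshold itself counts as the active side, matching the
    equal-or-lower activation rule): inactive (d1 > thr, d2 > thr),
    intermediate (d1 > thr, d2 ≤ thr), active (d1 ≤ thr, d2 ≤ thr), and the
    mechanistically disallowed quadrant (d1 ≤ thr, d2 > thr) reported as
    ``forbidden_path``.
    """
    x, y = fes.cv1_axis, fes.cv2_axis
    if not (x.min() < threshold < x.max() and y.min() < threshold < y.max()):
        raise GpcrSwitchError(
            f"grid [{x.min()}, {x.max()}]×[{y.min()}, {y.max()}] does not span "
            f"the {threshold} Å threshold"
        )
    X, Y = np.meshgrid(x, y, indexing="ij")
    out: dict[str, dict] = {}
    for region in STATE_REGIONS:
        m1 = X <= threshold if region.cv1_active else X > threshold
        m2 = Y <= threshold if region.cv2_active else Y > threshold
        mask = m1 & m2
        vals = np.where(mask, fes.values, np.inf)
        flat = int(np.argmin(vals))
        i, j = np.unravel_index(flat, vals.shape)
        out[region.name] = {
            "min_free_energy": float(vals[i, j]),
            "argmin": (float(x[i]), float(y[j])),
        }
    return out


def evaluate_cvs(top: TopologyMap, coords: np.ndarray) -> tuple[float, float]:
    """Evaluate both collective variables on a single structure."""
    traj = Trajectory(
        coords=np.asarray(coords, dtype=float)[None, :, :], times=np.array([0.0])
    )
    vals = []
    for sel_a, sel_b in CV_DEFINITIONS:
        d = distance_series(traj, sel_a.resolve(top), sel_b.resolve(top))
        vals.append(float(d[0]))
    return vals[0], vals[1]


def crystal_point(top: TopologyMap, reference_coords: np.ndarray) -> tuple[float, float]:
    """(d1, d2) of a reference structure — the crystal marker on the FES."""
    return evaluate_cvs(top, reference_coords)
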