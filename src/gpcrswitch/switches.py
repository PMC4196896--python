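"""Micro-switch distance series, threshold classification and engagement stats.

A micro-switch is a conserved residue motif whose local conformation tracks
receptor activation.  Each switch is measured as an interatomic distance per
frame and classified against a fixed threshold; the boundary is inclusive —
a distance exactly equal to the threshold counts as engaged for
``engaged_when="le_threshold"``.  Engagement percentages pooled over
replicates are frame-weighted (total engaged frames over total frames), not a
mean of per-replicate means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GpcrSwitchError
from .structure import BWIndex, TopologyMap, Trajectory, select_atom

#: default thresholds (Å): activation switches engage at ≤ 9.5 Å to helix 5;
#: the ionic lock closes at ≤ 5 Å; the Asp–Arg salt bridge forms at ≤ 4 Å
#: (standard salt-bridge criterion; configurable).
THRESHOLD_ACTIVATION = 9.5
THRESHOLD_IONIC_LOCK = 5.0
THRESHOLD_SALT_BRIDGE = 4.0


@dataclass(frozen=True)
class AtomSel:
    """A (BW index, atom role) selector resolved through a TopologyMap."""

    bw: str
    role: str

    def resolve(self, top: TopologyMap) -> "int | tuple[int, ...]":
        return select_atom(top, BWIndex.parse(self.bw), self.role)


@dataclass(frozen=True)
class SwitchDefinition:
    """A named distance metric with an optional engagement threshold.

    ``threshold=None`` marks a reporter: the distance is recorded but never
    binarized (used for the Y7.53 orientation scatter).
    """

    name: str
    sel_a: AtomSel
    sel_b: AtomSel
    threshold: "float | None"
    engaged_when: str = "le_threshold"  # or "gt_threshold"
    pair_reduction: str = "single_pair"  # or "min_over_pairs"

    def __post_init__(self) -> None:
        if self.threshold is not None and not self.threshold > 0:
            raise GpcrSwitchError(f"threshold must be > 0, got {self.threshold}")
        if self.engaged_when not in ("le_threshold", "gt_threshold"):
            raise GpcrSwitchError(f"bad engaged_when {self.engaged_when!r}")
        if self.pair_reduction not in ("single_pair", "min_over_pairs"):
            raise GpcrSwitchError(f"bad pair_reduction {self.pair_reduction!r}")


@dataclass
class SwitchSeries:
    """Per-frame distances and engaged flags for one switch in one replicate."""

    name: str
    replicate: "str | None"
    times: np.ndarray
    distances: np.ndarray
    states: "np.ndarray | None"  # boolean; None for unclassified reporters

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.times) != len(self.distances):
            raise GpcrSwitchError("times and distances lengths differ")
        if np.any(self.distances < 0):
            raise GpcrSwitchError("distances must be non-negative")
        if self.states is not None:
            self.states = np.asarray(self.states, dtype=bool)
            if len(self.states) != len(self.distances):
                raise GpcrSwitchError("states and distances lengths differ")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ps": self.times, "distance_A": self.distances}
        if self.states is not None:
            data["state"] = np.where(self.states, "engaged", "disengaged")
        return pd.DataFrame(data)


@dataclass
class EngagementSummary:
    """Engagement percentages per replicate plus the pooled, frame-weighted one."""

    name: str
    per_replicate: dict
    pooled_percent: float
    n_frames_total: int
    n_engaged_total: int


def distance_series(
    traj: Trajectory,
    idx_a: "int | Sequence[int]",
    idx_b: "int | Sequence[int]",
) -> np.ndarray:
    """Per-frame Euclidean distance in Å between two atoms (or atom sets).

    When either index is a set, the per-frame minimum over all cross pairs is
    returned.  Plain Euclidean distances — no minimum-image convention; the
    intramolecular separations measured here never span a periodic box.
    """
    a = np.atleast_1d(np.asarray(idx_a, dtype=int))
    b = np.atleast_1d(np.asarray(idx_b, dtype=int))
    pa = traj.coords[:, a, :]  # (F, na, 3)
    pb = traj.coords[:, b, :]  # (F, nb, 3)
    diff = pa[:, :, None, :] - pb[:, None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))  # (F, na, nb)
    return d.reshape(d.shape[0], -1).min(axis=1)


def classify(distances: np.ndarray, definition: SwitchDefinition) -> np.ndarray:
    """Boolean engaged flags; the threshold itself always classifies engaged
    under ``le_threshold`` (and disengaged under ``gt_threshold``)."""
    if definition.threshold is None:
        raise GpcrSwitchError(f"switch {definition.name!r} is an unclassified reporter")
    d = np.asarray(distances, dtype=float)
    if definition.engaged_when == "le_threshold":
        return d <= definition.threshold
    return d > definition.threshold


def evaluate_switch(
    traj: Trajectory,
    top: TopologyMap,
    definition: SwitchDefinition,
    replicate: "str | None" = None,
) -> SwitchSeries:
    """Resolve selectors, measure the distance series, classify if thresholded."""
    idx_a = definition.sel_a.resolve(top)
    idx_b = definition.sel_b.resolve(top)
    d = distance_series(traj, idx_a, idx_b)
    states = None if definition.threshold is None else classify(d, definition)
    return SwitchSeries(
        name=definition.name,
        replicate=replicate if replicate is not None else traj.replicate,
        times=traj.times,
        distances=d,
        states=states,
    )


def engagement_summary(series: "Iterable[SwitchSeries]") -> EngagementSummary:
    """Aggregate engagement over replicates of one switch.

    The pooled percentage is 100 · (Σ engaged frames) / (Σ frames) over the
    concatenated replicates, so replicates of unequal length contribute in
    proportion to their simulation time.
    """
    series = list(series)
    if not series:
        raise GpcrSwitchError("engagement_summary needs at least one series")
    names = {s.name for s in series}
    if len(names) > 1:
        raise GpcrSwitchError(f"mixed switch names {sorted(names)}")
    per_rep = {}
    total_frames = 0
    total_engaged = 0
    for i, s in enumerate(series):
        if s.states is None:
            raise GpcrSwitchError(f"series {s.name!r} is unclassified")
        n = len(s.states)
        k = int(np.count_nonzero(s.states))
        rep = s.replicate if s.replicate is not None else f"rep{i}"
        per_rep[rep] = 100.0 * k / n
        total_frames += n
        total_engaged += k
    return EngagementSummary(
        name=series[0].name,
        per_replicate=per_rep,
        pooled_percent=100.0 * total_engaged / total_frames,
        n_frames_total=total_frames,
        n_engaged_total=total_engaged,
    )


def transition_count(states: np.ndarray) -> int:
    """Number of consecutive-frame state changes in a boolean state series."""
    states = np.asarray(states, dtype=bool)
    if len(states) < 2:
        warnings.warn("transition_count on <2 frames is 0 by definition")
        return 0
    return int(np.count_nonzero(states[1:] != states[:-1]))


def builtin_switch_definitions(receptor: str = "") -> list[SwitchDefinition]:
    """The study's micro-switch metric set.

    * F6.44 activation: para ring carbon of F6.44 to Cα 5.50, engaged ≤ 9.5 Å.
    * F6.41 activation: para ring carbon of F6.41 to Cα 5.54, engaged ≤ 9.5 Å.
    * Ionic lock: Arg 3.50 guanidinium C to Glu 6.30 Cδ, closed ≤ 5 Å.
    * D3.49–R3.50 salt bridge: min over carboxylate-O × guanidinium-N pairs,
      formed ≤ 4.0 Å.
    * Y7.53 orientation: OH to Cα 3.50 and to Cα 2.40, reported unclassified.
    """
    return [
        SwitchDefinition(
            "F6.44_activation",
            AtomSel("6.44", "ring_C4"),
            AtomSel("5.50", "CA"),
            THRESHOLD_ACTIVATION,
        ),
        SwitchDefinition(
            "F6.41_activation",
            AtomSel("6.41", "ring_C4"),
            AtomSel("5.54", "CA"),
            THRESHOLD_ACTIVATION,
        ),
        SwitchDefinition(
            "ionic_lock",
            AtomSel("3.50", "arg_CE"),
            AtomSel("6.30", "glu_CD"),
            THRESHOLD_IONIC_LOCK,
        ),
        SwitchDefinition(
            "D3.49-R3.50_salt_bridge",
            AtomSel("3.49", "carboxylate_O_pair"),
            AtomSel("3.50", "guanidinium_N_set"),
            THRESHOLD_SALT_BRIDGE,
            pair_reduction="min_over_pairs",
        ),
        SwitchDefinition(
            "Y7.53_to_3.50", AtomSel("7.53", "tyr_OH"), AtomSel("3.50", "CA"), None
        ),
        SwitchDefinition(
            "Y7.53_to_2.40", AtomSel("7.53", "tyr_OH"), AtomSel("2.40", "CA"), None
        ),
    ]


def series_to_csv(series: SwitchSeries, path: "str | Path", header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        series.to_frame().to_csv(fh, index=False)


def summary_table(summaries: "Iterable[EngagementSummary]") -> pd.DataFrame:
    """Tidy engagement table: one row per switch with pooled percentage."""
    rows = [
        {
            "switch": s.name,
            "pooled_percent": s.pooled_percent,
            "n_frames": s.n_frames_total,
            **{f"percent_{k}": v for k, v in s.per_replicate.items()},
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
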