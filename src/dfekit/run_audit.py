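"""The correction process: landmark location and one-way-trip auditing.

A dissociation replica is usable only if it behaves as a *one-way trip*:
the CV leaves the bound-state region (crosses the boundary r_b of the
averaged FES) and never returns.  Replicas are classified as

* ``one_way``    — crossed r_b, never came back below r_b − hysteresis → keep;
* ``multi_trip`` — crossed r_b, later returned below r_b − hysteresis → reject;
* ``invasion``   — never crossed r_b and drifted more than 4 Å below r_0
  (motion opposite to dissociation) → reject;
* ``incomplete`` — never crossed r_b but stayed near the well → extend.

Landmarks (bound-state minimum r_0, boundary r_b) are read off the averaged
FES.  Because rejecting replicas changes the average, the audit can be
iterated (filter → re-average → re-locate) until the verdict set is stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .deposition_io import CVTrajectory, FESProfile
from .fes_reconstruction import EnsembleFES, average_fes

__all__ = [
    "Landmarks",
    "RunEvidence",
    "RunVerdict",
    "AuditError",
    "locate_landmarks",
    "classify_run",
    "audit_ensemble",
    "iterate_audit",
    "summarize_verdicts",
]

#: How far below r_0 a non-exiting run must drift to count as an invasion (Å).
INVASION_MARGIN = 4.0

#: Default hysteresis below r_b for "returned to the bound state" (Å);
#: suppresses jitter right at the boundary.
DEFAULT_HYSTERESIS = 0.5

#: Rise above the minimum that defines the inner wall of the primary
#: minimum (kcal/mol), used only for the invasion diagnostic.
INNER_WALL_RISE = 4.0

_ACTION_FOR = {
    "one_way": "keep",
    "multi_trip": "reject",
    "invasion": "reject",
    "incomplete": "extend",
}


class AuditError(RuntimeError):
    """Raised when the audit cannot proceed (e.g. no bound state, empty ensemble)."""


@dataclass(frozen=True)
class Landmarks:
    """Bound-state landmarks read off an averaged FES."""

    r0: float  # CV of the bound-state minimum (Å)
    rb: float  # bound/free boundary (Å)
    g_min: float  # averaged FES value at r0 (kcal/mol)
    inner_wall: float | None = None  # first CV left of r0 where g rises 4 kcal/mol

    def __post_init__(self) -> None:
        if not self.r0 < self.rb:
            raise ValueError(f"landmarks require r0 < rb, got r0={self.r0}, rb={self.rb}")


@dataclass(frozen=True)
class RunEvidence:
    """Per-run measurements backing a verdict."""

    first_crossing_time: float | None  # ps, first time CV > rb
    min_cv: float  # Å
    return_events: int  # completed excursions back below rb - hysteresis
    invasion_fraction: float  # share of deposited bias left of the inner wall


@dataclass(frozen=True)
class RunVerdict:
    run_id: str
    category: str  # one_way | multi_trip | invasion | incomplete
    action: str  # keep | reject | extend
    evidence: RunEvidence

    def __post_init__(self) -> None:
        if self.category not in _ACTION_FOR:
            raise ValueError(f"unknown category {self.category!r}")
        if self.action != _ACTION_FOR[self.category]:
            raise ValueError(
                f"category {self.category} requires action {_ACTION_FOR[self.category]}, "
                f"got {self.action}"
            )


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, values[0]), values, np.full(pad, values[-1])])
    return np.convolve(padded, kernel, mode="valid")[: len(values)]


def locate_landmarks(
    averaged: EnsembleFES | FESProfile,
    smooth_window: int = 5,
    plateau_tolerance: float = 0.1,
    boundary_min_rise: float = 1.0,
) -> Landmarks:
    """Locate r_0 and r_b on an averaged FES.

    r_0 is the grid point of the global minimum (ties toward smaller CV).
    r_b is the first grid point right of r_0 that is a local maximum of the
    moving-average-smoothed profile — required to dominate a +/- window
    neighborhood and to rise at least ``boundary_min_rise`` kcal/mol above
    the minimum, so grid-scale noise is not mistaken for the barrier.  If
    the profile rises monotonically, the first point within
    ``plateau_tolerance`` of the final plateau value is used instead.
    """
    profile = averaged.profile if isinstance(averaged, EnsembleFES) else averaged
    grid, g = profile.grid, profile.energies
    if len(grid) < 3:
        raise AuditError("averaged FES too short to locate landmarks")
    gs = _moving_average(g, smooth_window)
    i0 = int(np.argmin(gs))
    if i0 >= len(grid) - 1:
        raise AuditError("no bound state detected: profile decreases to the grid end")
    if i0 == 0 and np.all(np.diff(gs) >= -1e-12):
        raise AuditError("no bound state detected: profile is monotone, no interior minimum")
    # first neighborhood maximum right of the minimum, clearly above it
    irb = None
    w = max(smooth_window, 1)
    n = len(grid)
    for i in range(i0 + 1, n - 1):
        lo, hi = max(i - w, 0), min(i + w + 1, n)
        if gs[i] >= gs[lo:hi].max() - 1e-15 and gs[i] > gs[i0] + boundary_min_rise:
            irb = i
            break
    if irb is None:
        plateau = gs[-1]
        if plateau <= gs[i0] + 1e-12:
            raise AuditError("no bound state detected: profile never rises after minimum")
        rise = np.nonzero(gs[i0 + 1 :] >= plateau - plateau_tolerance)[0]
        if len(rise) == 0:
            raise AuditError("no bound state detected: no boundary found")
        irb = i0 + 1 + int(rise[0])
    # inner wall (diagnostic only): first point left of r0 risen 4 kcal/mol
    inner_wall = None
    for i in range(i0 - 1, -1, -1):
        if g[i] >= g[i0] + INNER_WALL_RISE:
            inner_wall = float(grid[i])
            break
    return Landmarks(
        r0=float(grid[i0]), rb=float(grid[irb]), g_min=float(g[i0]), inner_wall=inner_wall
    )


def _invasion_fraction(primitive: FESProfile | None, inner_wall: float | None) -> float:
    """Share of a replica's deposited bias lying left of the inner wall."""
    if primitive is None or inner_wall is None:
        return 0.0
    bias = -primitive.energies  # accumulated Gaussian energy, >= 0
    total = np.trapezoid(bias, primitive.grid)
    if total <= 0:
        return 0.0
    left = primitive.grid <= inner_wall
    if not left.any():
        return 0.0
    inner = np.trapezoid(bias[left], primitive.grid[left]) if left.sum() > 1 else 0.0
    return float(inner / total)


def classify_run(
    trajectory: CVTrajectory,
    primitive: FESProfile | None,
    landmarks: Landmarks,
    hysteresis: float = DEFAULT_HYSTERESIS,
) -> RunVerdict:
    """Classify one replica trajectory against the one-way-trip criteria.

    The classification depends only on the sequence of CV values (it is
    invariant to uniform time rescaling); times enter the evidence only.
    """
    if len(trajectory) == 0:
        raise ValueError(f"empty trajectory for run {trajectory.run_id}")
    v = trajectory.values
    t = trajectory.times
    rb, r0 = landmarks.rb, landmarks.r0
    exceed = np.nonzero(v > rb)[0]
    min_cv = float(v.min())

    # count completed excursions (above rb then back below rb - hysteresis)
    returns = 0
    above = False
    for x in v:
        if not above and x > rb:
            above = True
        elif above and x < rb - hysteresis:
            above = False
            returns += 1

    inv_frac = _invasion_fraction(primitive, landmarks.inner_wall)
    if len(exceed):
        first = int(exceed[0])
        evidence = RunEvidence(
            first_crossing_time=float(t[first]),
            min_cv=min_cv,
            return_events=returns,
            invasion_fraction=inv_frac,
        )
        came_back = np.any(v[first:] < rb - hysteresis)
        category = "multi_trip" if came_back else "one_way"
    else:
        evidence = RunEvidence(
            first_crossing_time=None,
            min_cv=min_cv,
            return_events=0,
            invasion_fraction=inv_frac,
        )
        category = "invasion" if min_cv < r0 - INVASION_MARGIN else "incomplete"
    return RunVerdict(
        run_id=trajectory.run_id,
        category=category,
        action=_ACTION_FOR[category],
        evidence=evidence,
    )


def audit_ensemble(
    runs: Sequence[tuple[CVTrajectory, FESProfile | None]],
    averaged: EnsembleFES,
    hysteresis: float = DEFAULT_HYSTERESIS,
) -> tuple[list[RunVerdict], list[str]]:
    """Audit every replica against landmarks from the given averaged FES.

    Returns one verdict per run plus the ids of the runs to keep.
    """
    landmarks = locate_landmarks(averaged)
    verdicts = [classify_run(traj, prim, landmarks, hysteresis) for traj, prim in runs]
    kept = [vd.run_id for vd in verdicts if vd.action == "keep"]
    return verdicts, kept


def iterate_audit(
    runs: Sequence[tuple[CVTrajectory, FESProfile]],
    hysteresis: float = DEFAULT_HYSTERESIS,
    max_iterations: int = 5,
) -> tuple[list[RunVerdict], list[str], EnsembleFES, int]:
    """Run the audit to a fixed point: filter → re-average → re-locate.

    Starts from the unfiltered average; stops when the kept set no longer
    changes or after ``max_iterations``.  Returns the final verdicts, kept
    ids, the averaged FES of the kept set, and the iteration count.
    """
    if not runs:
        raise AuditError("no replicas to audit")
    ids = [traj.run_id for traj, _ in runs]
    profiles = {traj.run_id: prim for traj, prim in runs}
    kept = list(ids)
    verdicts: list[RunVerdict] = []
    averaged = average_fes([profiles[i] for i in kept], kept)
    for iteration in range(1, max_iterations + 1):
        verdicts, new_kept = audit_ensemble(runs, averaged, hysteresis)
        if not new_kept:
            raise AuditError("audit rejected every replica; ensemble unusable")
        if new_kept == kept:
            return verdicts, kept, averaged, iteration
        kept = new_kept
        averaged = average_fes([profiles[i] for i in kept], kept)
    return verdicts, kept, averaged, max_iterations


def summarize_verdicts(verdicts: Sequence[RunVerdict]) -> dict[str, int]:
    """Category counts, in the style of an applied-corrections summary."""
    counts = {"one_way": 0, "multi_trip": 0, "invasion": 0, "incomplete": 0}
    for vd in verdicts:
        counts[vd.category] += 1
    return counts
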