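"""Domain types and tabular text I/O for deposition records, CV traces and FES tables.

Three whitespace-separated text dialects are defined here, one per artifact:

* ``.kerseq.tsv`` — the kernel sequence: one deposited Gaussian per row
  (time, center, width, height) with a ``#``-prefixed metadata header.
* ``.cv.tsv`` — the collective-variable trajectory (time, D).
* ``.fes.tsv`` — a tabulated free-energy surface g(D) on a uniform grid.

Every file must carry a units declaration ``# units=angstrom ps kcal/mol``;
readers reject files without it.  Numeric fields are written with ``repr``
so a write→read round trip is bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GaussianKernel",
    "KernelSequence",
    "CVTrajectory",
    "FESProfile",
    "FormatError",
    "read_kernel_sequence",
    "write_kernel_sequence",
    "read_cv_trajectory",
    "write_cv_trajectory",
    "read_fes",
    "write_fes",
]

UNITS_LINE = "angstrom ps kcal/mol"
_ACCEPTED_UNITS = {UNITS_LINE, "Å ps kcal/mol", "A ps kcal/mol"}

#: Relative tolerance for uniform-grid validation of FES tables.
GRID_RTOL = 1e-9

#: Number of grid points in a single-replica (primitive) FES table.
PRIMITIVE_FES_POINTS = 80


class FormatError(ValueError):
    """Raised when a deposition/FES/CV file violates its dialect or invariants."""


#: A half-harmonic wall lets the walker (and hence deposition centers)
#: penetrate slightly past the nominal wall position; validation allows
#: this much overshoot.
WALL_CENTER_TOL = 0.5


@dataclass(frozen=True)
class GaussianKernel:
    """One deposited Gaussian bias kernel.

    Attributes
    ----------
    time : float
        Chemical time of deposition (ps).
    center : float
        CV value d(t) at deposition (Å); the kernel is centred here.
    width : float
        Gaussian width sigma (Å).
    height : float
        Gaussian height h (kcal/mol).
    """

    time: float
    center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"kernel width must be > 0, got {self.width}")
        if not self.height > 0:
            raise ValueError(f"kernel height must be > 0, got {self.height}")
        if self.time < 0:
            raise ValueError(f"kernel time must be >= 0, got {self.time}")


@dataclass
class KernelSequence:
    """The time-ordered deposition history of one metadynamics replica."""

    run_id: str
    seed: int
    kernels: list[GaussianKernel]
    wall_position: float
    duration: float  # ns

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        times = [k.time for k in self.kernels]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"kernel times not strictly increasing in run {self.run_id}")
        for k in self.kernels:
            if not (0.0 <= k.center <= self.wall_position + WALL_CENTER_TOL):
                raise ValueError(
                    f"kernel center {k.center} outside [0, wall={self.wall_position}] "
                    f"in run {self.run_id}"
                )
        if self.wall_position <= 0:
            raise ValueError("wall_position must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def __len__(self) -> int:
        return len(self.kernels)

    # Convenience column views used throughout reconstruction.
    def centers(self) -> np.ndarray:
        return np.array([k.center for k in self.kernels], dtype=float)

    def widths(self) -> np.ndarray:
        return np.array([k.width for k in self.kernels], dtype=float)

    def heights(self) -> np.ndarray:
        return np.array([k.height for k in self.kernels], dtype=float)

    def times(self) -> np.ndarray:
        return np.array([k.time for k in self.kernels], dtype=float)


@dataclass
class CVTrajectory:
    """A sampled CV-versus-time trace for one replica."""

    run_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self, wall_position: float | None = None, tolerance: float = 1.0) -> None:
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"trajectory times not strictly increasing in run {self.run_id}")
        if len(self.values) and np.any(self.values < -tolerance):
            raise ValueError(f"negative CV values in run {self.run_id}")
        if wall_position is not None and len(self.values):
            if np.any(self.values > wall_position + tolerance):
                raise ValueError(
                    f"CV exceeds wall {wall_position} (+{tolerance} tolerance) in run {self.run_id}"
                )

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class FESProfile:
    """A free-energy surface g(D) tabulated on a uniform ascending grid.

    ``kind`` distinguishes single-replica (``primitive``) tables, which have
    exactly 80 rows and non-positive energies (the negated sum of positive
    Gaussians), from ensemble-averaged (``averaged``) tables whose grid size
    is determined by the averaging step.
    """

    grid: np.ndarray
    energies: np.ndarray
    kind: str  # "primitive" | "averaged"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.kind not in ("primitive", "averaged"):
            raise ValueError(f"unknown FES kind {self.kind!r}")
        if self.grid.shape != self.energies.shape or self.grid.ndim != 1:
            raise ValueError("grid and energies must be 1-D arrays of equal length")
        if len(self.grid) < 2:
            raise ValueError("FES needs at least 2 grid points")
        steps = np.diff(self.grid)
        if np.any(steps <= 0):
            raise ValueError("FES grid must be strictly ascending")
        h = steps[0]
        if np.any(np.abs(steps - h) > GRID_RTOL * max(abs(self.grid[0]), abs(self.grid[-1]), h)):
            raise ValueError("FES grid is not uniform")
        if self.kind == "primitive":
            if len(self.grid) != PRIMITIVE_FES_POINTS:
                raise ValueError(
                    f"primitive FES must have {PRIMITIVE_FES_POINTS} rows, got {len(self.grid)}"
                )
            if np.any(self.energies > 1e-12):
                raise ValueError("primitive FES energies must be <= 0 everywhere")

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def __len__(self) -> int:
        return len(self.grid)


# ---------------------------------------------------------------------------
# low-level header handling
# ---------------------------------------------------------------------------

def _parse_header_and_rows(path: Path) -> tuple[dict[str, str], list[tuple[int, list[str]]]]:
    header: dict[str, str] = {}
    rows: list[tuple[int, list[str]]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
                continue
            rows.append((lineno, line.split()))
    return header, rows


def _check_units(header: dict[str, str], path: Path) -> None:
    units = header.get("units")
    if units is None:
        raise FormatError(f"{path}: missing required '# units=' declaration")
    if units not in _ACCEPTED_UNITS:
        raise FormatError(
            f"{path}: unsupported units {units!r}; expected '{UNITS_LINE}'"
        )


def _floats(fields: Sequence[str], n: int, path: Path, lineno: int) -> list[float]:
    if len(fields) != n:
        raise FormatError(f"{path}:{lineno}: expected {n} columns, got {len(fields)}")
    try:
        return [float(f) for f in fields]
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: malformed numeric field ({exc})") from None


# ---------------------------------------------------------------------------
# kernel sequences
# ---------------------------------------------------------------------------

def read_kernel_sequence(path: str | Path) -> KernelSequence:
    """Read a ``.kerseq.tsv`` deposition record.

    The header must declare ``run_id``, ``seed``, ``wall_A``, ``duration_ns``
    and the units line; each data row is ``time_ps center_A width_A height_kcal``.
    """
    path = Path(path)
    header, rows = _parse_header_and_rows(path)
    _check_units(header, path)
    for key in ("run_id", "seed", "wall_A", "duration_ns"):
        if key not in header:
            raise FormatError(f"{path}: missing required header key '{key}'")
    kernels = []
    for lineno, fields in rows:
        t, c, w, h = _floats(fields, 4, path, lineno)
        try:
            kernels.append(GaussianKernel(time=t, center=c, width=w, height=h))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    try:
        return KernelSequence(
            run_id=header["run_id"],
            seed=int(header["seed"]),
            kernels=kernels,
            wall_position=float(header["wall_A"]),
            duration=float(header["duration_ns"]),
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_kernel_sequence(sequence: KernelSequence, path: str | Path) -> None:
    sequence.validate()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# run_id={sequence.run_id}\n")
        fh.write(f"# seed={sequence.seed}\n")
        fh.write(f"# wall_A={sequence.wall_position!r}\n")
        fh.write(f"# duration_ns={sequence.duration!r}\n")
        fh.write(f"# units={UNITS_LINE}\n")
        fh.write("# columns=time_ps center_A width_A height_kcal\n")
        for k in sequence.kernels:
            fh.write(f"{k.time!r}\t{k.center!r}\t{k.width!r}\t{k.height!r}\n")


# ---------------------------------------------------------------------------
# CV trajectories
# ---------------------------------------------------------------------------

def read_cv_trajectory(path: str | Path) -> CVTrajectory:
    path = Path(path)
    header, rows = _parse_header_and_rows(path)
    _check_units(header, path)
    if "run_id" not in header:
        raise FormatError(f"{path}: missing required header key 'run_id'")
    times, values = [], []
    for lineno, fields in rows:
        t, v = _floats(fields, 2, path, lineno)
        times.append(t)
        values.append(v)
    try:
        return CVTrajectory(run_id=header["run_id"], times=np.array(times), values=np.array(values))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_cv_trajectory(trajectory: CVTrajectory, path: str | Path) -> None:
    trajectory.validate()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# run_id={trajectory.run_id}\n")
        fh.write(f"# units={UNITS_LINE}\n")
        fh.write("# columns=time_ps D_A\n")
        for t, v in zip(trajectory.times, trajectory.values):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# FES tables
# ---------------------------------------------------------------------------

def read_fes(path: str | Path) -> FESProfile:
    path = Path(path)
    header, rows = _parse_header_and_rows(path)
    _check_units(header, path)
    kind = header.get("kind")
    if kind is None:
        raise FormatError(f"{path}: missing required header key 'kind'")
    grid, energies = [], []
    for lineno, fields in rows:
        d, g = _floats(fields, 2, path, lineno)
        grid.append(d)
        energies.append(g)
    try:
        return FESProfile(grid=np.array(grid), energies=np.array(energies), kind=kind)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_fes(profile: FESProfile, path: str | Path) -> None:
    """Write an FES table: one ``D g`` row per grid point at full precision."""
    profile.validate()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind={profile.kind}\n")
        fh.write(f"# units={UNITS_LINE}\n")
        fh.write("# columns=D_A g_kcal_per_mol\n")
        for d, g in zip(profile.grid, profile.energies):
            fh.write(f"{float(d)!r}\t{float(g)!r}\n")
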