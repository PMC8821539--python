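"""Reconstruction of free-energy surfaces from deposition records.

The free-energy estimate of one replica (its *primitive* FES) is the
negative image of its accumulated bias:

    g(D) = - sum_i h_i exp( -(D - d_i)^2 / (2 sigma_i^2) )

tabulated on 80 uniformly spaced points spanning the deposited range
(min to max kernel center, endpoints included, spacing = range/79).

An ensemble of primitive profiles is averaged on a common grid spanning
the union of the member ranges, with spacing no coarser than the finest
member spacing; members are resampled by linear interpolation inside
their own range and contribute zero outside it (no bias deposited there).
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .deposition_io import FESProfile, KernelSequence, PRIMITIVE_FES_POINTS

__all__ = [
    "EnsembleFES",
    "primitive_fes",
    "interpolate_linear",
    "average_fes",
    "evaluate_bias",
]


@dataclass
class EnsembleFES:
    """An averaged FES together with the bookkeeping of which replicas entered it."""

    profile: FESProfile
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.profile.kind != "averaged":
            raise ValueError("EnsembleFES profile must have kind='averaged'")
        if len(self.member_ids) < 1:
            raise ValueError("EnsembleFES needs at least one member")

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def grid(self) -> np.ndarray:
        return self.profile.grid

    @property
    def energies(self) -> np.ndarray:
        return self.profile.energies


def evaluate_bias(sequence: KernelSequence, D: np.ndarray) -> np.ndarray:
    """Total deposited Gaussian energy at point(s) ``D`` (a positive quantity)."""
    D = np.atleast_1d(np.asarray(D, dtype=float))
    c = sequence.centers()
    w = sequence.widths()
    h = sequence.heights()
    # (n_points, n_kernels) outer difference; toy-scale sequences are small
    # enough that chunking over grid points keeps memory modest.
    out = np.zeros(len(D))
    chunk = max(1, int(4e6 // max(len(c), 1)))
    for lo in range(0, len(D), chunk):
        d = D[lo : lo + chunk, None] - c[None, :]
        out[lo : lo + chunk] = (h * np.exp(-(d * d) / (2.0 * w * w))).sum(axis=1)
    return out


def primitive_fes(sequence: KernelSequence) -> FESProfile:
    """Rebuild the single-replica FES from its deposition record.

    The grid's first and last points are the minimum and maximum kernel
    centers; energies are the negated kernel sum at each grid point.
    """
    if len(sequence.kernels) == 0:
        raise ValueError(f"empty deposition history for run {sequence.run_id}")
    centers = sequence.centers()
    lo, hi = float(centers.min()), float(centers.max())
    if hi <= lo:
        raise ValueError(
            f"degenerate CV range [{lo}, {hi}] in run {sequence.run_id}: "
            "all kernels share one center"
        )
    grid = np.linspace(lo, hi, PRIMITIVE_FES_POINTS)
    energies = -evaluate_bias(sequence, grid)
    return FESProfile(grid=grid, energies=energies, kind="primitive")


def interpolate_linear(D: float, D1: float, g1: float, D2: float, g2: float) -> float:
    """Linear interpolation of g between the bracketing tabulated points.

    Requires ``D1 < D2`` and ``D`` inside ``[D1, D2]``.
    """
    if not D1 < D2:
        raise ValueError(f"need D1 < D2, got D1={D1}, D2={D2}")
    if not (D1 <= D <= D2):
        raise ValueError(f"query D={D} outside [{D1}, {D2}]")
    return g1 + (D - D1) * (g2 - g1) / (D2 - D1)


def average_fes(
    members: Sequence[FESProfile], member_ids: Sequence[str] | None = None
) -> EnsembleFES:
    """Average primitive profiles onto a common grid.

    The common grid spans [min of member starts, max of member ends]; the
    number of intervals is chosen so the spacing is uniform, hits both
    endpoints exactly, and is no coarser than the finest member spacing.
    Each member is linearly interpolated inside its own range and counted
    as zero outside it; the ensemble value is the arithmetic mean over all
    members at every grid point.
    """
    members = list(members)
    if not members:
        raise ValueError("average_fes requires at least one member profile")
    if member_ids is None:
        member_ids = [f"member-{i}" for i in range(len(members))]
    member_ids = list(member_ids)
    if len(member_ids) != len(members):
        raise ValueError("member_ids length must match members")

    lo = min(float(m.grid[0]) for m in members)
    hi = max(float(m.grid[-1]) for m in members)
    finest = min(m.spacing for m in members)
    n_intervals = max(1, int(np.ceil((hi - lo) / finest - 1e-9)))
    grid = np.linspace(lo, hi, n_intervals + 1)

    resampled = np.stack(
        [np.interp(grid, m.grid, m.energies, left=0.0, right=0.0) for m in members]
    )
    # exact per-point summation keeps the average bit-identical under any
    # permutation of the member list
    energies = np.array([math.fsum(col) for col in resampled.T]) / len(members)
    profile = FESProfile(grid=grid, energies=energies, kind="averaged")
    return EnsembleFES(profile=profile, member_ids=member_ids)
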