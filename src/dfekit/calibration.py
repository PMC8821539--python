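"""DFE → binding-free-energy calibration and affinity bookkeeping.

DFE is not itself a binding free energy: it measures the work to push a
complex out of its bound-state well and omits the free-state terms.  It is,
however, strongly linearly correlated with experimental affinities, so a
one-parameter family

    dG_c = slope * DFE + intercept

fitted by ordinary least squares of dG_e on DFE converts DFE values into
calibrated predictions.  Experimental free energies come from dissociation
constants via dG_e = kT ln(Kd) (Kd in molar, 1 M standard state, 310 K).

Two benchmark panels ship with the package (``load_ppc_table`` — 19
protein–protein complexes with DFE, Kd and correction bookkeeping;
``load_plc_table`` — per-target least-squares statistics for eight
protein–ligand panels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, kT as _kT

__all__ = [
    "AffinityRecord",
    "CalibrationFit",
    "kd_to_dg",
    "dg_to_kd",
    "fit_calibration",
    "published_calibration",
    "predict_dg",
    "aggregate_panel",
    "load_ppc_table",
    "load_plc_table",
    "records_from_frame",
]

#: Printed ∆G_e values are given to 2 d.p.; consistency checks allow this slack.
_KD_CONSISTENCY_TOL = 0.011


@dataclass
class AffinityRecord:
    """Per-complex affinity bookkeeping."""

    complex_id: str
    dfe: float  # kcal/mol (post-correction)
    dg_exp: float  # kcal/mol
    dfe_nc: float | None = None  # pre-correction DFE
    kd: float | None = None  # molar
    dg_calc: float | None = None  # calibrated prediction
    dfe_err: float | None = None  # sampling standard error of DFE

    def __post_init__(self) -> None:
        if self.kd is not None:
            if self.kd <= 0:
                raise ValueError(f"{self.complex_id}: Kd must be positive, got {self.kd}")
            implied = kd_to_dg(self.kd)
            if abs(round(implied, 2) - round(self.dg_exp, 2)) > _KD_CONSISTENCY_TOL:
                raise ValueError(
                    f"{self.complex_id}: dg_exp={self.dg_exp} inconsistent with "
                    f"kT ln(Kd)={implied:.2f} at {DEFAULT_TEMPERATURE_K} K"
                )


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary-least-squares calibration of dG_e on DFE."""

    slope: float
    intercept: float  # kcal/mol
    r_squared: float
    r: float
    se: float  # residual standard error, kcal/mol (n - 2 dof)
    n: int
    excluded_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("calibration needs at least 3 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of range: {self.r_squared}")
        if abs(self.r_squared - self.r * self.r) > 1e-9:
            raise ValueError("r^2 and r are inconsistent")


def published_calibration() -> CalibrationFit:
    """The benchmark calibration line at its published (printed) precision:
    dG_c = 0.4512*DFE - 1.02, fitted on the 18 protein–protein complexes
    after excluding the 3SGB outlier."""
    r2 = 0.84
    return CalibrationFit(
        slope=0.4512,
        intercept=-1.02,
        r_squared=r2,
        r=math.sqrt(r2),
        se=1.61,
        n=18,
        excluded_ids=("3SGB",),
    )


def kd_to_dg(kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Experimental binding free energy kT ln(Kd), Kd in molar (kcal/mol)."""
    if kd <= 0:
        raise ValueError(f"Kd must be positive, got {kd}")
    return _kT(temperature) * math.log(kd)


def dg_to_kd(dg: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Inverse of :func:`kd_to_dg`."""
    return math.exp(dg / _kT(temperature))


def fit_calibration(
    records: Sequence[AffinityRecord],
    exclude: Iterable[str] = (),
) -> CalibrationFit:
    """Least-squares fit of dg_exp on dfe, optionally excluding named outliers."""
    exclude = tuple(exclude)
    used = [r for r in records if r.complex_id not in exclude]
    if len(used) < 3:
        raise ValueError(f"need >= 3 records after exclusion, have {len(used)}")
    x = np.array([r.dfe for r in used], dtype=float)
    y = np.array([r.dg_exp for r in used], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all DFE values identical")
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    ssr = float(np.sum(residuals**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        r=math.copysign(math.sqrt(max(r2, 0.0)), slope),
        se=math.sqrt(ssr / (n - 2)),
        n=n,
        excluded_ids=exclude,
    )


def predict_dg(fit: CalibrationFit, dfe: float) -> float:
    """Calibrated binding free energy dG_c = slope*DFE + intercept (kcal/mol)."""
    return fit.slope * dfe + fit.intercept


def aggregate_panel(
    per_target: Sequence[tuple[str, float, float]],
    substitute: dict[str, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """Unweighted mean (r², se) across per-target panels.

    ``substitute`` maps a target id to replacement (r², se) values, e.g. the
    outlier-excluded variant of one panel.
    """
    if not per_target:
        raise ValueError("aggregate_panel requires at least one panel")
    substitute = substitute or {}
    r2s, ses = [], []
    for target, r2, se in per_target:
        if target in substitute:
            r2, se = substitute[target]
        r2s.append(r2)
        ses.append(se)
    return float(np.mean(r2s)), float(np.mean(ses))


# ---------------------------------------------------------------------------
# bundled benchmark panels
# ---------------------------------------------------------------------------

def _read_bundled(name: str) -> pd.DataFrame:
    text = resources.files("dfekit.data").joinpath(name).read_text(encoding="utf-8")
    return pd.read_csv(StringIO(text), sep="\t", comment="#")


def load_ppc_table() -> pd.DataFrame:
    """The 19-complex protein–protein benchmark panel (DFE, Kd, corrections)."""
    return _read_bundled("ppc_affinity_panel.tsv")


def load_plc_table() -> pd.DataFrame:
    """Per-target least-squares statistics of the eight protein–ligand panels."""
    return _read_bundled("plc_target_panels.tsv")


def records_from_frame(frame: pd.DataFrame) -> list[AffinityRecord]:
    """Build :class:`AffinityRecord` objects from a panel table.

    Requires ``complex_id``, ``dfe`` and ``dg_exp`` columns; ``kd``,
    ``dfe_nc`` and ``dfe_err`` are picked up when present.
    """
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            AffinityRecord(
                complex_id=str(row.complex_id),
                dfe=float(row.dfe),
                dg_exp=float(row.dg_exp),
                kd=float(row.kd) if hasattr(row, "kd") and pd.notna(row.kd) else None,
                dfe_nc=float(row.dfe_nc) if hasattr(row, "dfe_nc") and pd.notna(row.dfe_nc) else None,
                dg_calc=float(row.dg_calc) if hasattr(row, "dg_calc") and pd.notna(row.dg_calc) else None,
                dfe_err=float(row.dfe_err) if hasattr(row, "dfe_err") and pd.notna(row.dfe_err) else None,
            )
        )
    return records
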