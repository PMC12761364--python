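"""Docking-evaluation arithmetic: pose RMSD, Docking Accuracy, binding-energy
decomposition totals, and the predicted-activity-vs-binding-energy regression.

This module does not run docking.  It evaluates docking *output*:

* **Docking Accuracy (DA)** summarizes a redocking run from the cumulative
  fractions of poses within two RMSD limits ``l < h`` (default 2 and 3 Å):
  ``DA = f_l + 0.5·(f_h − f_l)`` with ``f_l`` the fraction of poses at
  RMSD ≤ l and ``f_h`` the fraction at RMSD ≤ h.  Poses inside the tight
  limit count fully, poses in the (l, h] shoulder count half; DA ∈ [0, 1]
  with 1 meaning every pose reproduces the crystallographic geometry within
  l.  Both intervals are closed at the limit, matching the usual "up to l Å"
  / "between l and h Å" banding.
* **Binding-energy totals**: the AutoDock-style decomposition partitions the
  score into electrostatic, van der Waals, internal and torsional terms; the
  reported binding free energy is the sum of the *interaction* terms —
  electrostatic + vdW + torsional — excluding the ligand-internal term.  The
  checker recomputes the sum and flags reported totals that deviate by more
  than 0.015 kcal/mol (values printed to 0.01 kcal/mol round-trip within
  that band).
* **Activity–energy regression**: ordinary least squares of predicted pKi
  (three replicates per compound, one per property channel) on binding
  energy, with parameter standard errors, R²/adjusted R², internally
  studentized residuals, and the replicate-based lack-of-fit F test
  ``F = (SS_lof/(k−2)) / (SS_pe/(N−k))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PoseRMSDSet",
    "EnergyDecomposition",
    "ActivityEnergyPoint",
    "ActivityEnergyFit",
    "CONSISTENCY_TOL",
    "pose_rmsd",
    "docking_accuracy",
    "total_binding_energy",
    "check_energy_table",
    "activity_energy_fit",
    "read_pose_csv",
    "read_energy_csv",
]

#: Half-band for reported-total agreement, kcal/mol.
CONSISTENCY_TOL = 0.015


@dataclass(frozen=True)
class PoseRMSDSet:
    """RMSDs (Å) of redocked poses against the crystallographic reference."""

    rmsds: np.ndarray
    l: float = 2.0
    h: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rmsds", np.asarray(self.rmsds, dtype=float))
        if self.rmsds.ndim != 1:
            raise ValueError("rmsds must be a 1-d sequence")
        if np.any(self.rmsds < 0):
            raise ValueError("RMSD values must be >= 0")
        if not self.l < self.h:
            raise ValueError(f"require l < h, got l={self.l}, h={self.h}")


@dataclass(frozen=True)
class EnergyDecomposition:
    """One AutoDock-style binding-energy decomposition row (kcal/mol)."""

    name: str
    electrostatic: float
    vdw: float
    internal: float
    torsional: float
    reported_total: float | None = None


@dataclass(frozen=True)
class ActivityEnergyPoint:
    """One candidate: binding energy (x) and three per-channel pKi predictions (y)."""

    id: str
    energy: float
    pki_replicates: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.pki_replicates) != 3:
            raise ValueError(
                f"point {self.id!r}: expected exactly 3 pKi replicates "
                f"(one per property channel), got {len(self.pki_replicates)}"
            )


def pose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD between two matched-order coordinate sets, no superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def docking_accuracy(pose_set: PoseRMSDSet) -> float:
    """``DA = f_l + 0.5·(f_h − f_l)`` from cumulative in-limit fractions."""
    r = pose_set.rmsds
    if r.size == 0:
        raise ValueError("empty pose set")
    f_l = float(np.mean(r <= pose_set.l))
    f_h = float(np.mean(r <= pose_set.h))
    return f_l + 0.5 * (f_h - f_l)


def total_binding_energy(
    decomp: EnergyDecomposition, tol: float = CONSISTENCY_TOL
) -> tuple[float, bool | None]:
    """Interaction-term total and, when a reported total exists, its consistency.

    ``total = electrostatic + vdW + torsional`` (internal energy excluded).
    Returns ``(total, consistent)`` with ``consistent = None`` when no
    reported total is available to check against.
    """
    for term in ("electrostatic", "vdw", "torsional"):
        value = getattr(decomp, term)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"row {decomp.name!r}: missing {term} term")
    total = decomp.electrostatic + decomp.vdw + decomp.torsional
    if decomp.reported_total is None:
        return total, None
    return total, bool(abs(total - decomp.reported_total) <= tol)


def check_energy_table(
    rows: Sequence[EnergyDecomposition], tol: float = CONSISTENCY_TOL
) -> pd.DataFrame:
    """Recompute totals for a whole table; one row per input with a flag."""
    records = []
    for row in rows:
        total, consistent = total_binding_energy(row, tol=tol)
        records.append(
            {
                "name": row.name,
                "computed_total": total,
                "reported_total": row.reported_total,
                "consistent": consistent,
            }
        )
    return pd.DataFrame(records)


@dataclass(frozen=True)
class ActivityEnergyFit:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    r2_adj: float
    lof_f: float
    lof_p: float
    max_studentized_residual: float
    n_obs: int
    n_groups: int


def activity_energy_fit(points: Sequence[ActivityEnergyPoint]) -> ActivityEnergyFit:
    """OLS of all replicate pKi observations on binding energy, with lack-of-fit.

    All 3k replicate observations enter the regression.  The lack-of-fit test
    partitions the residual sum of squares into pure error (within replicate
    groups at each distinct energy) and lack of fit; zero pure error with a
    nonzero lack-of-fit yields F = +inf with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    if len({round(p.energy, 12) for p in points}) < 3:
        raise ValueError("need at least 3 distinct binding-energy values")
    x = np.repeat([p.energy for p in points], 3)
    y = np.concatenate([np.asarray(p.pki_replicates, float) for p in points])
    res = sm.OLS(y, sm.add_constant(x)).fit()

    groups: dict[float, list[float]] = {}
    for xi, yi in zip(x, y):
        groups.setdefault(xi, []).append(yi)
    k = len(groups)
    n_obs = y.size
    ss_pe = sum(float(((np.array(v) - np.mean(v)) ** 2).sum()) for v in groups.values())
    ss_res = float(res.ssr)
    ss_lof = max(ss_res - ss_pe, 0.0)
    # absorb floating-point residue on exactly-linear data
    tiny = 1e-12 * max(float(res.centered_tss), 1.0)
    if ss_lof <= tiny:
        ss_lof = 0.0
    df_lof, df_pe = k - 2, n_obs - k
    if ss_pe == 0.0:
        if ss_lof > 0.0:
            warnings.warn("zero pure error with nonzero lack-of-fit; F reported as inf", stacklevel=2)
            lof_f, lof_p = math.inf, 0.0
        else:
            lof_f, lof_p = 0.0, 1.0
    else:
        lof_f = (ss_lof / df_lof) / (ss_pe / df_pe)
        lof_p = float(sps.f.sf(lof_f, df_lof, df_pe))

    if ss_res <= tiny:
        max_stud = 0.0
    else:
        max_stud = float(np.abs(OLSInfluence(res).resid_studentized_internal).max())
    return ActivityEnergyFit(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        lof_f=lof_f,
        lof_p=lof_p,
        max_studentized_residual=max_stud,
        n_obs=n_obs,
        n_groups=k,
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_pose_csv(path: str | Path, l: float = 2.0, h: float = 3.0) -> PoseRMSDSet:
    """Read a pose table (columns ``pose_id, rmsd``) into a :class:`PoseRMSDSet`."""
    df = pd.read_csv(path)
    if "rmsd" not in df.columns:
        raise ValueError(f"{path}: expected an 'rmsd' column")
    return PoseRMSDSet(rmsds=df["rmsd"].to_numpy(float), l=l, h=h)


def read_energy_csv(path: str | Path) -> list[EnergyDecomposition]:
    """Read an energy-decomposition table.

    Expected columns: ``sample, electrostatic, vdw, internal, torsional`` and
    optionally ``delta_g`` (the reported total).
    """
    df = pd.read_csv(path)
    required = {"sample", "electrostatic", "vdw", "internal", "torsional"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for _, row in df.iterrows():
        reported = float(row["delta_g"]) if "delta_g" in df.columns and pd.notna(row.get("delta_g")) else None
        rows.append(
            EnergyDecomposition(
                name=str(row["sample"]),
                electrostatic=float(row["electrostatic"]),
                vdw=float(row["vdw"]),
                internal=float(row["internal"]),
                torsional=float(row["torsional"]),
                reported_total=reported,
            )
        )
    return rows
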