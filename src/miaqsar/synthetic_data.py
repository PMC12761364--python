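"""Synthetic congeneric datasets with planted structure–activity effects.

No public dataset accompanies the triketone series this pipeline emulates, so
every stage is exercised on generated data whose ground truth is known.  The
generator mirrors the structure of a ~59-compound congeneric series: a shared
triketone-like scaffold with four substituent positions (R1..R4), pKi
responses near the reference range (baseline 7.0, per-substituent additive
effects within ±0.8 pKi units) and Gaussian assay noise (default sd 0.2 pKi
units).  The default effect pattern follows the qualitative
structure–activity picture for this compound class: methoxy and chloro at R3
are the strongest activity enhancers, halogens at R2 and methyl at R4 help
mildly, and alkyl groups at R1 hurt (steric penalty).

Additivity is deliberate: image descriptors of stamped substituents are
themselves additive presence indicators, so the planted effects are exactly
recoverable by a linear latent-variable model and parameter-recovery tests
have a well-defined target.

Fixtures for the docking-evaluation arithmetic (pose RMSD sets with
prescribed band occupancies, energy-decomposition tables with controlled
inconsistencies) are generated here as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .docking_eval import EnergyDecomposition, PoseRMSDSet
from .scaffold import TRIKETONE, ScaffoldTemplate, assemble_sketch
from .structure_io import ActivityRecord, MoleculeSketch, write_activities, write_sketches

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "DEFAULT_POOLS",
    "DEFAULT_EFFECTS",
    "generate_dataset",
    "generate_pose_set",
    "generate_energy_table",
    "write_dataset",
]

DEFAULT_POOLS: dict[str, tuple[str, ...]] = {
    "R1": ("H", "CH3", "C2H5"),
    "R2": ("H", "Cl", "F"),
    "R3": ("H", "OCH3", "Cl", "CH3"),
    "R4": ("H", "CH3", "Cl"),
}

DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "R1": {"H": 0.0, "CH3": -0.45, "C2H5": -0.70},
    "R2": {"H": 0.0, "Cl": 0.30, "F": 0.22},
    "R3": {"H": 0.0, "OCH3": 0.80, "Cl": 0.65, "CH3": 0.15},
    "R4": {"H": 0.0, "CH3": 0.25, "Cl": 0.10},
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic congeneric series."""

    n_samples: int = 59
    scaffold: ScaffoldTemplate = field(default_factory=lambda: TRIKETONE)
    pools: Mapping[str, Sequence[str]] = field(default_factory=lambda: dict(DEFAULT_POOLS))
    effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {p: dict(e) for p, e in DEFAULT_EFFECTS.items()}
    )
    baseline_pki: float = 7.0
    noise_sd: float = 0.2
    jitter_sd: float = 0.0
    seed: int = 0
    outlier_index: int | None = None
    outlier_shift_sd: float = 5.0
    #: When set, clean-sample noise draws are redrawn until |z| <= this bound
    #: (in sd units).  Used with ``outlier_index`` so that a planted shift is
    #: the *only* extreme residual and outlier-detection checks are exact.
    truncate_noise_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise_sd and jitter_sd must be >= 0")
        for pos, pool in self.pools.items():
            if not pool:
                raise ValueError(f"empty substituent pool at {pos}")
            missing = set(pool) - set(self.effects.get(pos, {}))
            if missing:
                raise ValueError(f"effects table does not cover {sorted(missing)} at {pos}")
        if self.outlier_index is not None and not 0 <= self.outlier_index < self.n_samples:
            raise ValueError("outlier_index out of range")


@dataclass
class SyntheticDataset:
    sketches: list[MoleculeSketch]
    activities: list[ActivityRecord]
    ground_truth: dict
    config: GeneratorConfig


def _truncated_normal(rng: np.random.Generator, bound_sd: float | None) -> float:
    z = float(rng.standard_normal())
    if bound_sd is not None:
        while abs(z) > bound_sd:
            z = float(rng.standard_normal())
    return z


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a congeneric series with known per-substituent effects.

    Substituents are drawn uniformly per position;
    ``pKi = baseline + Σ effects + N(0, noise_sd)``; sketches are the scaffold
    with the drawn fragments stamped on.  Bit-reproducible for a given seed.
    """
    cfg = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    positions = cfg.scaffold.positions

    sketches: list[MoleculeSketch] = []
    activities: list[ActivityRecord] = []
    samples_truth: list[dict] = []
    for i in range(cfg.n_samples):
        assignment = {
            pos: cfg.pools[pos][int(rng.integers(len(cfg.pools[pos])))] for pos in positions
        }
        effect_sum = sum(cfg.effects[pos][assignment[pos]] for pos in positions)
        z = _truncated_normal(rng, cfg.truncate_noise_sd)
        noise = cfg.noise_sd * z
        pki = cfg.baseline_pki + effect_sum + noise
        outlier_shift = 0.0
        if cfg.outlier_index == i:
            outlier_shift = cfg.outlier_shift_sd * cfg.noise_sd
            pki += outlier_shift

        sid = f"S{i + 1:03d}"
        jitter = None
        if cfg.jitter_sd > 0:
            n_atoms = len(cfg.scaffold.core_atoms) + sum(
                len(_fragment_atoms(assignment[pos])) for pos in positions
            )
            raw = rng.standard_normal((n_atoms, 2))
            jitter = cfg.jitter_sd * np.clip(raw, -2.0, 2.0)
        sketches.append(assemble_sketch(cfg.scaffold, assignment, sid, jitter=jitter))
        activities.append(ActivityRecord(sid, pki=pki))
        samples_truth.append(
            {
                "id": sid,
                "assignment": assignment,
                "effect_sum": effect_sum,
                "noise": noise,
                "outlier_shift": outlier_shift,
                "pki": pki,
            }
        )

    ground_truth = {
        "baseline_pki": cfg.baseline_pki,
        "noise_sd": cfg.noise_sd,
        "effects": {p: dict(cfg.effects[p]) for p in positions},
        "pools": {p: list(cfg.pools[p]) for p in positions},
        "outlier_index": cfg.outlier_index,
        "samples": samples_truth,
    }
    return SyntheticDataset(sketches, activities, ground_truth, cfg)


def _fragment_atoms(name: str):
    from .scaffold import FRAGMENTS

    return FRAGMENTS[name].atoms


def generate_pose_set(
    n: int,
    frac_within_l: float,
    frac_within_h: float,
    seed: int = 0,
    l: float = 2.0,
    h: float = 3.0,
) -> PoseRMSDSet:
    """Pose-RMSD fixture hitting prescribed cumulative band fractions.

    ``frac_within_l`` / ``frac_within_h`` are the cumulative fractions of
    poses with RMSD ≤ l and ≤ h; counts are rounded, values drawn uniformly
    inside each band (strictly away from the band edges so that closed-interval
    boundary handling is never exercised by accident).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= frac_within_l <= frac_within_h <= 1.0):
        raise ValueError(
            f"inconsistent fractions: need 0 <= frac_within_l <= frac_within_h <= 1, "
            f"got ({frac_within_l}, {frac_within_h})"
        )
    n_l = int(round(frac_within_l * n))
    n_h = int(round(frac_within_h * n)) - n_l
    n_out = n - n_l - n_h
    rng = np.random.default_rng(seed)
    band_width = h - l
    rmsds = np.concatenate(
        [
            rng.uniform(0.1 * l, 0.95 * l, n_l),
            rng.uniform(l + 0.02 * band_width, h - 0.02 * band_width, n_h),
            rng.uniform(h + 0.05, h + 2.0, n_out),
        ]
    )
    rng.shuffle(rmsds)
    return PoseRMSDSet(rmsds=rmsds, l=l, h=h)


def generate_energy_table(
    rows: int,
    seed: int = 0,
    perturbations: Mapping[int, float] | None = None,
) -> tuple[list[EnergyDecomposition], dict[int, float]]:
    """Energy-decomposition fixture with controlled reported-total errors.

    Every row gets random (rounded) electrostatic/vdW/internal/torsional terms
    and a reported total equal to the interaction sum, except rows listed in
    ``perturbations`` whose reported total is shifted by the given magnitude
    (which must exceed the 0.015 kcal/mol consistency tolerance to be
    detectable).  Returns the rows and the applied perturbation record.
    """
    if rows < 1:
        raise ValueError("rows must be >= 1")
    perturbations = dict(perturbations or {})
    for idx, mag in perturbations.items():
        if not 0 <= idx < rows:
            raise ValueError(f"perturbation index {idx} out of range")
        if abs(mag) <= 0.015:
            raise ValueError(f"perturbation {mag} at row {idx} is below the consistency tolerance")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(rows):
        electro = round(float(rng.uniform(-3.5, -0.5)), 2)
        vdw = round(float(rng.uniform(-10.0, -3.0)), 2)
        internal = round(float(rng.uniform(-2.5, 0.0)), 2)
        torsional = round(float(rng.uniform(0.3, 2.2)), 2)
        total = round(electro + vdw + torsional, 2)
        if i in perturbations:
            total = round(total + perturbations[i], 2)
        out.append(
            EnergyDecomposition(
                name=f"E{i + 1}",
                electrostatic=electro,
                vdw=vdw,
                internal=internal,
                torsional=torsional,
                reported_total=total,
            )
        )
    return out, perturbations


def write_dataset(dataset: SyntheticDataset, outdir: str | Path, dialect: str = "sdf") -> dict[str, Path]:
    """Write sketches (SDF/MOL2), activities (CSV) and ground truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sketches": outdir / f"sketches.{dialect}",
        "activities": outdir / "activities.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_sketches(dataset.sketches, paths["sketches"], dialect=dialect)
    write_activities(dataset.activities, paths["activities"])
    paths["ground_truth"].write_text(json.dumps(dataset.ground_truth, indent=1))
    return paths
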