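"""I/O for aligned 2D congeneric structure sketches and activity tables.

Image-based (MIA) QSAR operates on *drawings*: every compound of a congeneric
series is sketched on a shared 2D template so that the common core occupies
identical coordinates in every record.  Descriptors are pixel intensities of
those drawings, which makes the whole method alignment-sensitive by
construction — hence the explicit :func:`check_alignment` gate that must pass
before any rasterization.

Structures are exchanged as SDF (V2000, via RDKit with sanitization disabled,
since sketches are schematic and not valence-checked molecules) or as minimal
TRIPOS MOL2.  Activities are CSV tables of Ki (mol/L) and/or pKi = −log10(Ki).
Atomic periodic properties (Pauling electronegativity, Bondi van der Waals
radius) used to weight pixel intensities come from a bundled, versioned CSV
table; looking up an element absent from the table is always an error, never
a silent default.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Bond",
    "MoleculeSketch",
    "ActivityRecord",
    "ElementPropertyTable",
    "AlignmentResult",
    "CHANNELS",
    "read_sketches",
    "write_sketches",
    "check_alignment",
    "load_activities",
    "write_activities",
    "pki_from_ki",
]

#: The three periodic-property channels used to weight pixel intensities.
CHANNELS = ("r_vdw", "epsilon", "ratio")


class Atom(NamedTuple):
    element: str
    x: float
    y: float


class Bond(NamedTuple):
    a: int
    b: int
    order: int


@dataclass
class MoleculeSketch:
    """One aligned 2D drawing of a congener on the shared template.

    ``substituent_labels`` optionally maps a position tag (``R1`` .. ``R4``)
    to the set of atom indices belonging to the substituent stamped at that
    position; the synthetic generator populates it so that planted effects
    can be traced back to pixels.
    """

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    substituent_labels: dict[str, frozenset[int]] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sketch id must be non-empty")
        for i, at in enumerate(self.atoms):
            if not (math.isfinite(at.x) and math.isfinite(at.y)):
                raise ValueError(f"sketch {self.id!r}: atom {i} has non-finite coordinates")
        n = len(self.atoms)
        for bd in self.bonds:
            if not (0 <= bd.a < n and 0 <= bd.b < n) or bd.a == bd.b:
                raise ValueError(f"sketch {self.id!r}: bond {bd} references invalid atom indices")

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([(a.x, a.y) for a in self.atoms], dtype=float).reshape(len(self.atoms), 2)


@dataclass(frozen=True)
class ActivityRecord:
    """Inhibitory activity of one compound: Ki in mol/L and/or pKi = −log10 Ki."""

    id: str
    ki: float | None = None
    pki: float | None = None

    def __post_init__(self) -> None:
        if self.ki is None and self.pki is None:
            raise ValueError(f"record {self.id!r}: neither ki nor pki given")
        if self.ki is not None:
            if not (self.ki > 0):
                raise ValueError(f"record {self.id!r}: ki must be > 0, got {self.ki}")
            implied = pki_from_ki(self.ki)
            if self.pki is None:
                object.__setattr__(self, "pki", implied)
            elif abs(self.pki - implied) > 1e-6:
                raise ValueError(
                    f"record {self.id!r}: inconsistent ki/pki pair "
                    f"(pki={self.pki}, -log10(ki)={implied})"
                )


def pki_from_ki(ki: float) -> float:
    """pKi = −log10(Ki), Ki in mol/L; strictly decreasing in Ki."""
    if ki <= 0:
        raise ValueError(f"ki must be > 0, got {ki}")
    return -math.log10(ki)


@dataclass(frozen=True)
class ElementPropertyTable:
    """Per-element (Pauling electronegativity ε, Bondi r_vdW in Å) table.

    The derived ``ratio`` channel is r_vdW/ε.  Which radius compilation the
    original MIA software used is not public, so the table is an ordinary CSV
    the user can swap out.
    """

    properties: Mapping[str, tuple[float, float]]  # element -> (epsilon, r_vdw)

    def __post_init__(self) -> None:
        for el, (eps, rv) in self.properties.items():
            if not (eps > 0 and rv > 0):
                raise ValueError(f"element {el!r}: epsilon and r_vdw must be > 0")

    def _get(self, element: str) -> tuple[float, float]:
        try:
            return self.properties[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} is not in the property table; add it explicitly"
            ) from None

    def epsilon(self, element: str) -> float:
        return self._get(element)[0]

    def r_vdw(self, element: str) -> float:
        return self._get(element)[1]

    def ratio(self, element: str) -> float:
        eps, rv = self._get(element)
        return rv / eps

    def channel_value(self, element: str, channel: str) -> float:
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
        return getattr(self, channel)(element)

    def channel_max(self, channel: str) -> float:
        return max(self.channel_value(el, channel) for el in self.properties)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ElementPropertyTable":
        props: dict[str, tuple[float, float]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                props[row["element"].strip()] = (float(row["epsilon"]), float(row["r_vdw"]))
        return cls(props)

    @classmethod
    def default(cls) -> "ElementPropertyTable":
        ref = resources.files("miaqsar.data").joinpath("element_properties.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


# ---------------------------------------------------------------------------
# SDF via RDKit
# ---------------------------------------------------------------------------

_Z_TOL = 1e-6
_SUBST_PROP = "substituents"


def _encode_labels(labels: Mapping[str, frozenset[int]]) -> str:
    return ";".join(
        f"{pos}:{','.join(str(i) for i in sorted(idx))}" for pos, idx in sorted(labels.items())
    )


def _decode_labels(text: str) -> dict[str, frozenset[int]]:
    out: dict[str, frozenset[int]] = {}
    for part in text.split(";"):
        if not part:
            continue
        pos, _, idxs = part.partition(":")
        out[pos] = frozenset(int(i) for i in idxs.split(",") if i)
    return out


def _sketch_to_rdkit(sketch: MoleculeSketch):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    rw = Chem.RWMol()
    for at in sketch.atoms:
        a = Chem.Atom(at.element)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for bd in sketch.bonds:
        if bd.order not in order_map:
            raise ValueError(f"sketch {sketch.id!r}: unsupported bond order {bd.order}")
        rw.AddBond(bd.a, bd.b, order_map[bd.order])
    mol = rw.GetMol()
    conf = Chem.Conformer(len(sketch.atoms))
    for i, at in enumerate(sketch.atoms):
        conf.SetAtomPosition(i, Point3D(at.x, at.y, 0.0))
    mol.AddConformer(conf)
    mol.UpdatePropertyCache(strict=False)
    mol.SetProp("_Name", sketch.id)
    if sketch.substituent_labels:
        mol.SetProp(_SUBST_PROP, _encode_labels(sketch.substituent_labels))
    return mol


def _rdkit_to_sketch(mol, index: int) -> MoleculeSketch:
    from rdkit import Chem

    order_map = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2, Chem.BondType.TRIPLE: 3}
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
    if not name:
        raise ValueError(f"record {index}: missing molecule name (used as id)")
    conf = mol.GetConformer()
    zs = [conf.GetAtomPosition(i).z for i in range(mol.GetNumAtoms())]
    if zs and (max(zs) - min(zs)) > _Z_TOL:
        raise ValueError(
            f"record {index} ({name!r}): non-constant z coordinates — this reader only "
            "accepts flat 2D sketches; flatten the structure first"
        )
    atoms = [
        Atom(mol.GetAtomWithIdx(i).GetSymbol(), conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y)
        for i in range(mol.GetNumAtoms())
    ]
    bonds = []
    for bd in mol.GetBonds():
        if bd.GetBondType() not in order_map:
            raise ValueError(f"record {index} ({name!r}): unsupported bond type {bd.GetBondType()}")
        bonds.append(Bond(bd.GetBeginAtomIdx(), bd.GetEndAtomIdx(), order_map[bd.GetBondType()]))
    labels = _decode_labels(mol.GetProp(_SUBST_PROP)) if mol.HasProp(_SUBST_PROP) else None
    return MoleculeSketch(name, atoms, bonds, labels)


def _read_sdf(path: Path) -> list[MoleculeSketch]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    sketches = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"malformed SDF record at index {i} in {path}")
        sketches.append(_rdkit_to_sketch(mol, i))
    return sketches


def _write_sdf(sketches: Sequence[MoleculeSketch], path: Path) -> None:
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for sk in sketches:
        writer.write(_sketch_to_rdkit(sk))
    writer.close()


# ---------------------------------------------------------------------------
# Minimal TRIPOS MOL2 (RDKit has no MOL2 writer)
# ---------------------------------------------------------------------------

def _write_mol2(sketches: Sequence[MoleculeSketch], path: Path) -> None:
    lines: list[str] = []
    for sk in sketches:
        lines.append("@<TRIPOS>MOLECULE")
        lines.append(sk.id)
        lines.append(f"{len(sk.atoms)} {len(sk.bonds)} 0 0 0")
        lines.append("SMALL")
        lines.append("NO_CHARGES")
        lines.append("")
        lines.append("@<TRIPOS>ATOM")
        for i, at in enumerate(sk.atoms, 1):
            lines.append(
                f"{i:>6} {at.element + str(i):<8} {at.x:>12.6f} {at.y:>12.6f} {0.0:>12.6f} {at.element}"
            )
        lines.append("@<TRIPOS>BOND")
        for j, bd in enumerate(sk.bonds, 1):
            lines.append(f"{j:>6} {bd.a + 1:>5} {bd.b + 1:>5} {bd.order}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _read_mol2(path: Path) -> list[MoleculeSketch]:
    text = Path(path).read_text()
    blocks = [b for b in text.split("@<TRIPOS>MOLECULE") if b.strip()]
    sketches = []
    for idx, block in enumerate(blocks):
        try:
            sketches.append(_parse_mol2_block(block, idx))
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed MOL2 record at index {idx} in {path}: {exc}") from exc
    return sketches


def _parse_mol2_block(block: str, index: int) -> MoleculeSketch:
    lines = block.splitlines()
    # first non-empty line after the MOLECULE tag is the name
    body = [ln for ln in lines if ln.strip() != ""]
    name = body[0].strip()
    section = None
    atoms: list[Atom] = []
    zs: list[float] = []
    bonds: list[Bond] = []
    for ln in lines:
        stripped = ln.strip()
        if stripped.startswith("@<TRIPOS>"):
            section = stripped[len("@<TRIPOS>"):]
            continue
        if not stripped or section not in ("ATOM", "BOND"):
            continue
        parts = stripped.split()
        if section == "ATOM":
            if len(parts) < 6:
                raise ValueError(f"malformed MOL2 record at index {index}: bad ATOM line {ln!r}")
            x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
            element = parts[5].split(".")[0]
            atoms.append(Atom(element, x, y))
            zs.append(z)
        else:
            if len(parts) < 4:
                raise ValueError(f"malformed MOL2 record at index {index}: bad BOND line {ln!r}")
            try:
                order = int(parts[3])
            except ValueError:
                raise ValueError(
                    f"record {index} ({name!r}): unsupported MOL2 bond type {parts[3]!r}"
                ) from None
            bonds.append(Bond(int(parts[1]) - 1, int(parts[2]) - 1, order))
    if zs and (max(zs) - min(zs)) > _Z_TOL:
        raise ValueError(
            f"record {index} ({name!r}): non-constant z coordinates — flatten to 2D first"
        )
    return MoleculeSketch(name, atoms, bonds)


# ---------------------------------------------------------------------------
# Public read/write + alignment + activities
# ---------------------------------------------------------------------------

def read_sketches(path: str | Path, dialect: str = "sdf") -> list[MoleculeSketch]:
    """Read aligned 2D sketches from an SDF or MOL2 file.

    Coordinates are read as-is (no re-layout); ids must be unique; 3D records
    (non-constant z) are rejected with advice to flatten.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "sdf":
        sketches = _read_sdf(path)
    elif dialect == "mol2":
        sketches = _read_mol2(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'sdf' or 'mol2'")
    seen: set[str] = set()
    for sk in sketches:
        if sk.id in seen:
            raise ValueError(f"duplicate sketch id {sk.id!r} in {path}")
        seen.add(sk.id)
    return sketches


def write_sketches(sketches: Sequence[MoleculeSketch], path: str | Path, dialect: str = "sdf") -> None:
    path = Path(path)
    if dialect == "sdf":
        _write_sdf(sketches, path)
    elif dialect == "mol2":
        _write_mol2(sketches, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'sdf' or 'mol2'")


@dataclass(frozen=True)
class AlignmentResult:
    passed: bool
    tol: float
    max_deviation: dict[str, float] = field(default_factory=dict)

    def worst(self) -> float:
        return max(self.max_deviation.values()) if self.max_deviation else 0.0


def check_alignment(
    sketches: Sequence[MoleculeSketch],
    core_atom_map: Sequence[int] | Mapping[str, Sequence[int]],
    tol: float = 1e-3,
) -> AlignmentResult:
    """Verify that the congeneric-core atoms coincide across all sketches.

    ``core_atom_map`` is either one index sequence shared by all sketches or a
    per-id mapping.  The first sketch is the reference; a sketch fails when any
    core atom deviates by more than ``tol`` template units (Euclidean).
    Sketches are copies of one hand-drawn template, so deviations indicate a
    data error rather than noise — hence the strict default tolerance.
    """
    if not sketches:
        raise ValueError("no sketches given")

    def indices_for(sk: MoleculeSketch) -> Sequence[int]:
        idx = core_atom_map[sk.id] if isinstance(core_atom_map, Mapping) else core_atom_map
        for i in idx:
            if not 0 <= i < len(sk.atoms):
                raise ValueError(f"sketch {sk.id!r}: core atom index {i} out of range")
        return idx

    ref = sketches[0]
    ref_xy = ref.coordinates[list(indices_for(ref))]
    deviations: dict[str, float] = {}
    for sk in sketches:
        xy = sk.coordinates[list(indices_for(sk))]
        if xy.shape != ref_xy.shape:
            raise ValueError(f"sketch {sk.id!r}: core atom count differs from reference")
        dev = float(np.linalg.norm(xy - ref_xy, axis=1).max()) if len(xy) else 0.0
        deviations[sk.id] = dev
    passed = all(d <= tol for d in deviations.values())
    return AlignmentResult(passed, tol, deviations)


def load_activities(
    path: str | Path,
    sketch_ids: Iterable[str] | None = None,
) -> list[ActivityRecord]:
    """Load an activity CSV with columns ``id`` plus ``ki`` and/or ``pki``.

    pKi is computed as −log10(Ki) when only Ki is given.  If ``sketch_ids`` is
    supplied, activity ids with no sketch counterpart trigger a warning (the
    join is left to the caller).
    """
    df = pd.read_csv(path)
    if "id" not in df.columns or not ({"ki", "pki"} & set(df.columns)):
        raise ValueError(f"{path}: expected columns 'id' plus 'ki' and/or 'pki'")
    records = []
    for _, row in df.iterrows():
        ki = float(row["ki"]) if "ki" in df.columns and pd.notna(row.get("ki")) else None
        pki = float(row["pki"]) if "pki" in df.columns and pd.notna(row.get("pki")) else None
        records.append(ActivityRecord(str(row["id"]), ki=ki, pki=pki))
    if sketch_ids is not None:
        known = set(sketch_ids)
        orphans = [r.id for r in records if r.id not in known]
        if orphans:
            warnings.warn(f"activity records with no sketch counterpart: {orphans}", stacklevel=2)
    return records


def write_activities(records: Sequence[ActivityRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"id": [r.id for r in records], "ki": [r.ki for r in records], "pki": [r.pki for r in records]}
    ).to_csv(path, index=False)
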