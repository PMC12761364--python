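"""Shared drawing template: a triketone-like scaffold with four R positions.

Both the synthetic-data generator and the candidate-design stage stamp
substituent fragments onto the same hand-laid-out 2D template, mimicking how
a congeneric series is sketched for image-based QSAR: the core occupies fixed
template coordinates in every compound, substituents hang off four anchor
points (R1..R4) placed far enough apart that their rendered disks never
overlap each other or the core.  Fragment atom positions are expressed in a
local frame (along/perpendicular to the outward core→anchor direction) so the
same fragment definition works at every position.

Coordinates are template units; the default canvas (432 × 300 px at 10 px per
unit, origin offset (30, 30)) keeps every disk of every library fragment fully
inside the canvas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .imaging import CanvasSpec
from .structure_io import Atom, Bond, MoleculeSketch

__all__ = [
    "Fragment",
    "ScaffoldTemplate",
    "FRAGMENTS",
    "TRIKETONE",
    "assemble_sketch",
    "substituent_pixel_boxes",
]

#: Minimum allowed distance (template units) between a fragment atom and any
#: core atom it is not bonded to; closer means the drawing would be ambiguous.
MIN_CORE_SEPARATION = 2.5


@dataclass(frozen=True)
class Fragment:
    """A substituent drawn relative to its attachment point.

    ``atoms`` are (element, d_along, d_perp) offsets: the first atom sits at
    the anchor (d_along = d_perp = 0) and bonds to the core; ``bonds`` are
    intra-fragment (local index, local index, order).
    """

    name: str
    atoms: tuple[tuple[str, float, float], ...]
    bonds: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"fragment {self.name!r} has no atoms")
        if self.atoms[0][1:] != (0.0, 0.0):
            raise ValueError(f"fragment {self.name!r}: first atom must sit at the anchor")


FRAGMENTS: dict[str, Fragment] = {
    "H": Fragment("H", (("H", 0.0, 0.0),)),
    "F": Fragment("F", (("F", 0.0, 0.0),)),
    "Cl": Fragment("Cl", (("Cl", 0.0, 0.0),)),
    "Br": Fragment("Br", (("Br", 0.0, 0.0),)),
    "CH3": Fragment("CH3", (("C", 0.0, 0.0),)),
    "C2H5": Fragment("C2H5", (("C", 0.0, 0.0), ("C", 1.5, 0.8)), ((0, 1, 1),)),
    "OCH3": Fragment("OCH3", (("O", 0.0, 0.0), ("C", 1.5, 0.8)), ((0, 1, 1),)),
    "OH": Fragment("OH", (("O", 0.0, 0.0), ("H", 1.2, 0.6)), ((0, 1, 1),)),
    "NO2": Fragment(
        "NO2", (("N", 0.0, 0.0), ("O", 1.4, 0.9), ("O", 1.4, -0.9)), ((0, 1, 2), (0, 2, 1))
    ),
}


@dataclass(frozen=True)
class ScaffoldTemplate:
    """Fixed core drawing plus substituent anchor geometry."""

    id: str
    core_atoms: tuple[Atom, ...]
    core_bonds: tuple[Bond, ...]
    anchors: Mapping[str, tuple[float, float]]  # position tag -> template xy
    attach_from: Mapping[str, int]  # position tag -> core atom index

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(sorted(self.anchors))

    def core_indices(self) -> list[int]:
        return list(range(len(self.core_atoms)))


def _ring_atom(cx: float, cy: float, r: float, angle_deg: float) -> Atom:
    a = math.radians(angle_deg)
    return Atom("C", cx + r * math.cos(a), cy + r * math.sin(a))


def _default_triketone() -> ScaffoldTemplate:
    cx, cy, r = 18.0, 12.0, 3.0
    ring = [_ring_atom(cx, cy, r, ang) for ang in (0, 60, 120, 180, 240, 300)]
    # three exocyclic carbonyl oxygens on alternating ring carbons
    oxy = []
    for idx in (0, 2, 4):
        at = ring[idx]
        ux, uy = (at.x - cx) / r, (at.y - cy) / r
        oxy.append(Atom("O", at.x + 2.0 * ux, at.y + 2.0 * uy))
    atoms = tuple(ring + oxy)
    bonds = tuple(
        [Bond(i, (i + 1) % 6, 1) for i in range(6)]
        + [Bond(0, 6, 2), Bond(2, 7, 2), Bond(4, 8, 2)]
    )
    anchors = {"R1": (29.0, 20.0), "R2": (29.0, 4.0), "R3": (7.0, 20.0), "R4": (7.0, 4.0)}
    attach_from = {"R1": 1, "R2": 5, "R3": 2, "R4": 4}
    return ScaffoldTemplate("triketone_v1", atoms, bonds, anchors, attach_from)


#: The default congeneric-core template.
TRIKETONE = _default_triketone()


def assemble_sketch(
    scaffold: ScaffoldTemplate,
    assignment: Mapping[str, str | Fragment],
    sketch_id: str,
    jitter: np.ndarray | None = None,
) -> MoleculeSketch:
    """Stamp one fragment per position onto the scaffold.

    ``assignment`` maps every scaffold position to a fragment (by library name
    or instance).  ``jitter`` (n_atoms_total × 2, applied after assembly) is
    used by the generator to emulate imperfect redrawing.  Fragment atoms that
    land too close to a core atom raise an error naming the position.
    """
    missing = set(scaffold.positions) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing positions: {sorted(missing)}")

    atoms = list(scaffold.core_atoms)
    bonds = list(scaffold.core_bonds)
    labels: dict[str, frozenset[int]] = {}
    core_xy = np.array([(a.x, a.y) for a in scaffold.core_atoms])

    for pos in scaffold.positions:
        frag = assignment[pos]
        if isinstance(frag, str):
            try:
                frag = FRAGMENTS[frag]
            except KeyError:
                raise ValueError(f"unknown fragment {assignment[pos]!r} at {pos}") from None
        ax, ay = scaffold.anchors[pos]
        attach_idx = scaffold.attach_from[pos]
        src = scaffold.core_atoms[attach_idx]
        ux, uy = ax - src.x, ay - src.y
        norm = math.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm
        vx, vy = -uy, ux
        base = len(atoms)
        for el, d_along, d_perp in frag.atoms:
            x = ax + d_along * ux + d_perp * vx
            y = ay + d_along * uy + d_perp * vy
            d = np.hypot(core_xy[:, 0] - x, core_xy[:, 1] - y).min()
            if d < MIN_CORE_SEPARATION:
                raise ValueError(
                    f"fragment {frag.name!r} at position {pos} collides with the core "
                    f"(closest approach {d:.2f} template units)"
                )
            atoms.append(Atom(el, x, y))
        bonds.append(Bond(attach_idx, base, 1))
        for i, j, order in frag.bonds:
            bonds.append(Bond(base + i, base + j, order))
        labels[pos] = frozenset(range(base, len(atoms)))

    if jitter is not None:
        jitter = np.asarray(jitter, float)
        if jitter.shape != (len(atoms), 2):
            raise ValueError(f"jitter shape {jitter.shape} does not match atom count {len(atoms)}")
        atoms = [Atom(a.element, a.x + dx, a.y + dy) for a, (dx, dy) in zip(atoms, jitter)]

    return MoleculeSketch(sketch_id, atoms, bonds, labels)


def substituent_pixel_boxes(
    scaffold: ScaffoldTemplate,
    spec: CanvasSpec,
    half_width: float = 4.0,
) -> dict[str, tuple[int, int, int, int]]:
    """Pixel bounding box (row0, row1, col0, col1), inclusive, per position.

    ``half_width`` (template units) covers the largest library fragment plus
    the largest atom disk radius; boxes are clipped to the canvas.
    """
    boxes = {}
    for pos, (ax, ay) in scaffold.anchors.items():
        c, r = spec.to_pixel(ax, ay)
        d = half_width * spec.scale
        boxes[pos] = (
            max(0, int(math.floor(r - d))),
            min(spec.height - 1, int(math.ceil(r + d))),
            max(0, int(math.floor(c - d))),
            min(spec.width - 1, int(math.ceil(c + d))),
        )
    return boxes
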