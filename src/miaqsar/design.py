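"""Candidate design: enumerate substituent combinations and rank predictions.

Interpretation maps (VIP and coefficient plots refolded into image space)
point at substituent positions and groups that drive activity; turning that
evidence into a shortlist of favored substituents per position is a human
judgement call informed by the maps and the literature, so the shortlist is
an *input* here.  This module enumerates the Cartesian product of the
shortlists on the shared scaffold template, predicts each candidate's pKi
with the three per-channel models, aggregates mean ± standard deviation
across channels, and ranks the candidates against a reference compound
(e.g. mesotrione, predicted pKi 7.699 in this compound class).

Candidates are drawn on the same template grid as the training sketches —
image descriptors are alignment-sensitive, so no automatic layout is ever
applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import CanvasSpec, rasterize, unfold
from .qsar_model import PLSModel, predict
from .scaffold import FRAGMENTS, Fragment, ScaffoldTemplate, assemble_sketch
from .structure_io import CHANNELS, ElementPropertyTable, MoleculeSketch

__all__ = [
    "SubstituentSpec",
    "CandidateRecord",
    "enumerate_candidates",
    "predict_candidates",
    "rank_vs_reference",
    "candidates_to_dataframe",
]

#: Reference pKi used by default when ranking candidates.
MESOTRIONE_PKI = 7.699


@dataclass(frozen=True)
class SubstituentSpec:
    """A favored substituent at one position, as chosen from the MIA maps."""

    position: str
    name: str
    fragment: Fragment


@dataclass
class CandidateRecord:
    """One designed structure with per-channel predictions and their spread."""

    id: str
    sketch: MoleculeSketch
    assignment: dict[str, str]
    pki_by_channel: dict[str, float]
    mean_pki: float
    std_pki: float


def enumerate_candidates(
    scaffold: ScaffoldTemplate,
    substituent_sets: Mapping[str, Sequence[str | Fragment]],
    id_prefix: str = "P",
) -> list[MoleculeSketch]:
    """Cartesian product of per-position shortlists on the scaffold.

    Positions not listed keep hydrogen.  Duplicate compositions (the same
    fragment at every position) are dropped; the order is deterministic —
    positions sorted, shortlists in given order, product in lexicographic
    order.  A fragment whose geometry collides with the core propagates an
    error naming the position.
    """
    for pos, pool in substituent_sets.items():
        if pos not in scaffold.positions:
            raise ValueError(f"unknown position {pos!r}; scaffold has {scaffold.positions}")
        if not pool:
            raise ValueError(f"empty substituent set at {pos}")

    def _name(frag: str | Fragment) -> str:
        return frag if isinstance(frag, str) else frag.name

    varied = sorted(substituent_sets)
    pools = [substituent_sets[pos] for pos in varied]
    seen: set[tuple[str, ...]] = set()
    sketches: list[MoleculeSketch] = []
    counter = 0
    for combo in itertools.product(*pools):
        key = tuple(_name(f) for f in combo)
        if key in seen:
            continue
        seen.add(key)
        counter += 1
        assignment: dict[str, str | Fragment] = {pos: "H" for pos in scaffold.positions}
        assignment.update(dict(zip(varied, combo)))
        sketches.append(
            assemble_sketch(scaffold, assignment, f"{id_prefix}{counter:02d}")
        )
    return sketches


def predict_candidates(
    candidates: Sequence[MoleculeSketch],
    models_by_channel: Mapping[str, PLSModel],
    spec: CanvasSpec,
    properties: ElementPropertyTable | None = None,
) -> list[CandidateRecord]:
    """Rasterize and score each candidate with every per-channel model.

    Each model must carry the ``kept_columns`` of the descriptor block it was
    fitted on (set by ``fit_from_descriptor``); the candidate image is
    unfolded and restricted to those columns before prediction.  The record
    aggregates the three channel predictions as mean ± sample (ddof=1)
    standard deviation — the error bar convention for a three-measurement
    spread.
    """
    missing = set(CHANNELS) - set(models_by_channel)
    if missing:
        raise ValueError(f"missing models for channels: {sorted(missing)}")
    props = properties if properties is not None else ElementPropertyTable.default()
    records = []
    for sk in candidates:
        preds: dict[str, float] = {}
        for channel in CHANNELS:
            model = models_by_channel[channel]
            if model.kept_columns is None:
                raise ValueError(f"model for channel {channel!r} carries no kept_columns")
            # render with the channel the model was trained on (its own tag),
            # so a model is always applied to the image kind it consumes
            render_channel = model.channel or channel
            row = unfold(rasterize(sk, render_channel, spec, props))[model.kept_columns]
            preds[channel] = float(predict(model, row[None, :])[0])
        values = np.array([preds[c] for c in CHANNELS])
        labels = sk.substituent_labels or {}
        assignment = {pos: "" for pos in labels}
        records.append(
            CandidateRecord(
                id=sk.id,
                sketch=sk,
                assignment={pos: _assignment_name(sk, pos) for pos in sorted(labels)},
                pki_by_channel=preds,
                mean_pki=float(values.mean()),
                std_pki=float(values.std(ddof=1)),
            )
        )
    return records


def _assignment_name(sketch: MoleculeSketch, position: str) -> str:
    """Recover the fragment name at a position from the labelled atom set."""
    idx = sorted(sketch.substituent_labels[position])
    elements = tuple(sketch.atoms[i].element for i in idx)
    for name, frag in FRAGMENTS.items():
        if tuple(el for el, _, _ in frag.atoms) == elements:
            return name
    return "+".join(elements)


def rank_vs_reference(
    records: Sequence[CandidateRecord],
    reference_pki: float = MESOTRIONE_PKI,
) -> tuple[list[CandidateRecord], int]:
    """Sort candidates by mean predicted pKi (descending, id tie-break) and
    count how many beat the reference."""
    if not np.isfinite(reference_pki) and not reference_pki == -np.inf:
        raise ValueError("reference_pki must be finite or -inf")
    ordered = sorted(records, key=lambda r: (-r.mean_pki, r.id))
    count = sum(1 for r in records if r.mean_pki > reference_pki)
    return ordered, count


def candidates_to_dataframe(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Candidate table: id, per-channel pKi, mean and spread."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            **{f"pki_{c}": [r.pki_by_channel[c] for r in records] for c in CHANNELS},
            "mean_pki": [r.mean_pki for r in records],
            "std_pki": [r.std_pki for r in records],
        }
    )
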