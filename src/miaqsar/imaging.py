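"""Rasterization of aligned sketches into property-weighted pixel matrices.

Each compound drawing becomes a fixed-size single-channel image (default
432 × 300 pixels, intensities on the 0–765 summed-RGB scale): atoms are filled
disks whose radius is proportional to the element's van der Waals radius and
whose fill intensity encodes one periodic property (ε, r_vdW or r_vdW/ε);
bonds are 1-px dark lines.  Unfolding the images row-major and stacking the
compounds gives the descriptor block (X) of the MIA-QSAR model; columns that
never vary across the series (background, the shared core) carry no
information and are pruned, with the surviving column indices recorded so
model vectors can be refolded back into image space.

Rendering is deliberately exact and deterministic: integer pixel membership by
Euclidean distance, no anti-aliasing, overlaps resolved by painter's order
(the file's atom order).  The property→intensity mapping is
``765 · (1 − value/value_max)`` against a white background — darker means a
larger property value — and is a configuration choice: any strictly monotone
injective mapping carries the same information into the PLS model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.draw import line as _bresenham_line

from .structure_io import CHANNELS, ElementPropertyTable, MoleculeSketch

__all__ = [
    "CanvasSpec",
    "DescriptorMatrix",
    "rasterize",
    "atom_intensity",
    "build_descriptor_matrix",
    "unfold",
    "refold_full",
    "save_image_png",
    "save_descriptor_matrix",
    "load_descriptor_matrix",
]

#: Top of the summed-RGB intensity scale.
INTENSITY_MAX = 765.0


@dataclass(frozen=True)
class CanvasSpec:
    """Shared canvas geometry for one dataset.

    ``scale`` is pixels per template unit and ``origin`` the pixel offset of
    template coordinate (0, 0); pixel column = origin[0] + scale·x, pixel row
    = origin[1] + scale·y.  Every sketch of a dataset must be rendered with an
    identical CanvasSpec or the descriptor columns would not be comparable.
    """

    width: int = 432
    height: int = 300
    background: float = INTENSITY_MAX
    scale: float = 10.0
    origin: tuple[float, float] = (30.0, 30.0)
    bond_value: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas width and height must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """Template coordinates -> (col, row) pixel coordinates."""
        return self.origin[0] + self.scale * x, self.origin[1] + self.scale * y


def atom_intensity(element: str, channel: str, properties: ElementPropertyTable) -> float:
    """Map a periodic-property value to a pixel intensity in [0, 765].

    Linear, strictly decreasing in the property value relative to the table
    maximum: the heaviest-property element paints darkest, the background
    stays white.
    """
    value = properties.channel_value(element, channel)
    vmax = properties.channel_max(channel)
    return INTENSITY_MAX * (1.0 - value / vmax)


def rasterize(
    sketch: MoleculeSketch,
    channel: str,
    spec: CanvasSpec,
    properties: ElementPropertyTable | None = None,
) -> np.ndarray:
    """Render one sketch as a ``(height, width)`` float image.

    Bonds are drawn first (1-px Bresenham lines at ``spec.bond_value``), then
    atoms in file order as filled disks of radius ``scale · r_vdW(element)``
    pixels; later atoms overwrite earlier ones.  An atom whose disk does not
    fit inside the canvas is an error — clipping would silently corrupt the
    descriptor block.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    props = properties if properties is not None else ElementPropertyTable.default()
    img = np.full((spec.height, spec.width), float(spec.background))

    for bd in sketch.bonds:
        a0, a1 = sketch.atoms[bd.a], sketch.atoms[bd.b]
        c0, r0 = spec.to_pixel(a0.x, a0.y)
        c1, r1 = spec.to_pixel(a1.x, a1.y)
        rr, cc = _bresenham_line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        img[rr, cc] = spec.bond_value

    for i, at in enumerate(sketch.atoms):
        cx, cy = spec.to_pixel(at.x, at.y)
        radius = spec.scale * props.r_vdw(at.element)
        if cx - radius < 0 or cx + radius > spec.width - 1 or cy - radius < 0 or cy + radius > spec.height - 1:
            raise ValueError(
                f"sketch {sketch.id!r}: atom {i} ({at.element}) at pixel ({cx:.1f}, {cy:.1f}) "
                f"with radius {radius:.1f} px does not fit inside the {spec.width}x{spec.height} canvas"
            )
        value = atom_intensity(at.element, channel, props)
        r_lo, r_hi = int(np.floor(cy - radius)), int(np.ceil(cy + radius))
        c_lo, c_hi = int(np.floor(cx - radius)), int(np.ceil(cx + radius))
        rows = np.arange(r_lo, r_hi + 1)
        cols = np.arange(c_lo, c_hi + 1)
        dist2 = (rows[:, None] - cy) ** 2 + (cols[None, :] - cx) ** 2
        mask = dist2 <= radius**2
        img[r_lo : r_hi + 1, c_lo : c_hi + 1][mask] = value
    return img


def unfold(image: np.ndarray) -> np.ndarray:
    """Row-major unfolding of an image into a descriptor row."""
    return np.asarray(image, dtype=float).reshape(-1)


def refold_full(vector: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a full-length pixel vector."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != shape[0] * shape[1]:
        raise ValueError(f"vector length {vector.size} does not match image shape {shape}")
    return vector.reshape(shape)


@dataclass
class DescriptorMatrix:
    """Samples × kept-pixels descriptor block for one property channel."""

    X: np.ndarray  # (n_samples, n_kept)
    kept_columns: np.ndarray  # strictly increasing indices into the unfolded image
    channel: str
    spec: CanvasSpec
    ids: list[str] = field(default_factory=list)

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.spec.height, self.spec.width)

    @property
    def n_pixels(self) -> int:
        return self.spec.height * self.spec.width

    def refold(self, vector: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Place a kept-pixel vector back into image space; pruned pixels get ``fill``."""
        vector = np.asarray(vector, dtype=float)
        if vector.size != self.kept_columns.size:
            raise ValueError(
                f"vector length {vector.size} does not match kept column count {self.kept_columns.size}"
            )
        full = np.full(self.n_pixels, fill, dtype=float)
        full[self.kept_columns] = vector
        return full.reshape(self.image_shape)


def build_descriptor_matrix(
    sketches: Sequence[MoleculeSketch],
    channel: str,
    spec: CanvasSpec,
    properties: ElementPropertyTable | None = None,
) -> DescriptorMatrix:
    """Rasterize a series and assemble the pruned descriptor block.

    Rows follow the input sketch order; columns with zero variance across the
    series (identical intensity in every sample) are removed and the indices
    of the survivors recorded.
    """
    if not sketches:
        raise ValueError("no sketches given")
    props = properties if properties is not None else ElementPropertyTable.default()
    rows = [unfold(rasterize(sk, channel, spec, props)) for sk in sketches]
    full = np.vstack(rows)
    variable = full.max(axis=0) != full.min(axis=0)
    kept = np.flatnonzero(variable)
    return DescriptorMatrix(
        X=full[:, kept].copy(),
        kept_columns=kept,
        channel=channel,
        spec=spec,
        ids=[sk.id for sk in sketches],
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_image_png(image: np.ndarray, path: str | Path) -> None:
    """Export a single-channel image as 16-bit PNG (holds the 0–765 scale)."""
    from PIL import Image

    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    Image.fromarray(arr, mode="I;16").save(str(path))


def save_descriptor_matrix(dm: DescriptorMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.npz`` (arrays) plus ``<prefix>.json`` (canvas/channel metadata)."""
    prefix = Path(prefix)
    np.savez_compressed(prefix.with_suffix(".npz"), X=dm.X, kept_columns=dm.kept_columns)
    meta = {
        "channel": dm.channel,
        "ids": dm.ids,
        "spec": {
            "width": dm.spec.width,
            "height": dm.spec.height,
            "background": dm.spec.background,
            "scale": dm.spec.scale,
            "origin": list(dm.spec.origin),
            "bond_value": dm.spec.bond_value,
        },
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_descriptor_matrix(prefix: str | Path) -> DescriptorMatrix:
    prefix = Path(prefix)
    arrays = np.load(prefix.with_suffix(".npz"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    spec_meta = dict(meta["spec"])
    spec_meta["origin"] = tuple(spec_meta["origin"])
    return DescriptorMatrix(
        X=arrays["X"],
        kept_columns=arrays["kept_columns"],
        channel=meta["channel"],
        spec=CanvasSpec(**spec_meta),
        ids=list(meta["ids"]),
    )
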