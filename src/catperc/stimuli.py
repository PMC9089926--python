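"""Synthetic stimulus set: 64 coloured polygons on a black retina.

The task's visual world is the full factorial crossing of three categories
with four attributes each — colour (red, green, blue, yellow), shape
(square, circle, triangle, bar) and size (large, medium-large,
medium-small, small) — rendered as hard-edged, centred polygons on a
28×28 RGB canvas with a black background. Each image is unrolled
(row-major) into a 2,352-element "retina" vector that feeds the
perceptual network. Colours are pure saturated RGB, so every retina
entry is exactly 0 or 1, matching Bernoulli visible units.

Rendering is a pure function of the attribute triple: no anti-aliasing,
no jitter, no randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "COLOURS",
    "SHAPES",
    "SIZES",
    "IMAGE_SHAPE",
    "RETINA_SIZE",
    "AttributeTriple",
    "Stimulus",
    "render_stimulus",
    "generate_dataset",
    "dataset_retinas",
    "dataset_attribute_indices",
    "save_dataset",
    "load_dataset",
    "export_pngs",
]

COLOURS = ("red", "green", "blue", "yellow")
SHAPES = ("square", "circle", "triangle", "bar")
SIZES = ("large", "medium-large", "medium-small", "small")

IMAGE_SHAPE = (28, 28, 3)
RETINA_SIZE = 28 * 28 * 3  # 2352

_RGB = {
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
}

# Size levels span roughly 25%-85% of the 28-px frame; within every shape the
# four levels give strictly decreasing polygon pixel counts.
_SQUARE_SIDE = {"large": 24, "medium-large": 18, "medium-small": 12, "small": 7}
_CIRCLE_RADIUS = {"large": 12.0, "medium-large": 9.0, "medium-small": 6.0, "small": 3.5}
_TRIANGLE_HEIGHT = {"large": 24, "medium-large": 18, "medium-small": 12, "small": 7}
_BAR_WIDTH = {"large": 24, "medium-large": 18, "medium-small": 12, "small": 9}  # 3:1 aspect


@dataclass(frozen=True)
class AttributeTriple:
    """One of the 64 valid (colour, shape, size) combinations."""

    colour: str
    shape: str
    size: str

    def __post_init__(self) -> None:
        if self.colour not in COLOURS:
            raise ValueError(f"unknown colour {self.colour!r}; expected one of {COLOURS}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if self.size not in SIZES:
            raise ValueError(f"unknown size {self.size!r}; expected one of {SIZES}")

    @property
    def indices(self) -> tuple[int, int, int]:
        return COLOURS.index(self.colour), SHAPES.index(self.shape), SIZES.index(self.size)


@dataclass(frozen=True)
class Stimulus:
    """A rendered stimulus: attribute triple, RGB image and retina vector."""

    triple: AttributeTriple
    image: np.ndarray = field(repr=False)
    retina: np.ndarray = field(repr=False)


def _shape_mask(shape: str, size: str) -> np.ndarray:
    """Boolean 28×28 mask of the polygon's pixels, centred in the frame."""
    n = 28
    if shape == "square":
        s = _SQUARE_SIDE[size]
        lo = (n - s) // 2
        mask = np.zeros((n, n), dtype=bool)
        mask[lo : lo + s, lo : lo + s] = True
        return mask
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    if shape == "circle":
        r = _CIRCLE_RADIUS[size]
        return (xx - c) ** 2 + (yy - c) ** 2 <= r**2
    if shape == "triangle":
        # upward isosceles: apex at the top, base = height
        h = _TRIANGLE_HEIGHT[size]
        top = (n - h) // 2
        rel = yy - top  # row within the triangle, 0 at the apex
        halfwidth = (rel + 1.0) / 2.0
        return (rel >= 0) & (rel < h) & (np.abs(xx - c) <= halfwidth)
    if shape == "bar":
        w = _BAR_WIDTH[size]
        h = max(w // 3, 1)
        x0 = (n - w) // 2
        y0 = (n - h) // 2
        mask = np.zeros((n, n), dtype=bool)
        mask[y0 : y0 + h, x0 : x0 + w] = True
        return mask
    raise ValueError(f"unknown shape {shape!r}")


def render_stimulus(triple: AttributeTriple) -> Stimulus:
    """Render one triple to its 28×28×3 image and 2,352-element retina.

    Deterministic: repeated calls return identical arrays. Polygon pixels
    carry the triple's saturated RGB colour; background pixels are 0.
    """
    mask = _shape_mask(triple.shape, triple.size)
    image = np.zeros(IMAGE_SHAPE, dtype=np.float64)
    image[mask] = _RGB[triple.colour]
    retina = image.reshape(-1).copy()
    image.flags.writeable = False
    retina.flags.writeable = False
    return Stimulus(triple=triple, image=image, retina=retina)


def generate_dataset() -> list[Stimulus]:
    """All 64 stimuli in canonical order (colour-major, then shape, then size)."""
    return [
        render_stimulus(AttributeTriple(colour, shape, size))
        for colour in COLOURS
        for shape in SHAPES
        for size in SIZES
    ]


def dataset_retinas(stimuli: list[Stimulus]) -> np.ndarray:
    """Stack retina vectors into a (64, 2352) float array."""
    return np.stack([s.retina for s in stimuli])


def dataset_attribute_indices(stimuli: list[Stimulus]) -> np.ndarray:
    """(n, 3) integer array of (colour, shape, size) attribute indices."""
    return np.array([s.triple.indices for s in stimuli], dtype=np.intp)


def save_dataset(stimuli: list[Stimulus], path: str | Path) -> None:
    """Write the dataset to a single NPZ archive (retinas + attribute labels)."""
    path = Path(path)
    np.savez(
        path,
        retinas=dataset_retinas(stimuli),
        labels=dataset_attribute_indices(stimuli),
        meta=np.frombuffer(
            json.dumps({"colours": COLOURS, "shapes": SHAPES, "sizes": SIZES}).encode(),
            dtype=np.uint8,
        ),
    )


def load_dataset(path: str | Path) -> list[Stimulus]:
    """Load a saved dataset; retina vectors round-trip bit-exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no stimulus archive at {path}")
    with np.load(path) as npz:
        labels = npz["labels"]
        retinas = npz["retinas"]
    stimuli = []
    for (ci, si, zi), retina in zip(labels, retinas):
        triple = AttributeTriple(COLOURS[ci], SHAPES[si], SIZES[zi])
        rendered = render_stimulus(triple)
        if not np.array_equal(rendered.retina, retina):
            raise ValueError(f"stored retina for {triple} does not match its render")
        stimuli.append(rendered)
    return stimuli


def export_pngs(stimuli: list[Stimulus], out_dir: str | Path) -> list[Path]:
    """Export each stimulus as an 8-bit PNG for visual inspection."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in stimuli:
        name = f"{s.triple.colour}_{s.triple.shape}_{s.triple.size}.png"
        arr = (s.image * 255).astype(np.uint8)
        p = out_dir / name
        Image.fromarray(arr).save(p)
        paths.append(p)
    return paths
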