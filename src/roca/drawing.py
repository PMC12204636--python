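"""Stroke drawings, their JSON serialization, rasterization and preprocessing.

The screening battery collects free-hand drawings as ordered pen strokes on a
pixel canvas.  Downstream classification works on grayscale rasters, so this
module provides the bridge: a :class:`StrokeDrawing` container with a stable
one-file-per-drawing JSON format, a deterministic rasterizer, and a
preprocessing step that centers and rescales the ink before it reaches the
classifier.

Coordinate convention: origin at the top-left corner, x rightward, y downward,
0-based pixels (the common raster convention).  Per-point timestamps are
carried through serialization but ignored by rasterization: the battery scores
static drawings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

import numpy as np
from PIL import Image, ImageDraw

TASKS = ("cube", "infinity", "clock")

#: A single pen point: (x px, y px, t ms since drawing start).
Point = tuple[float, float, float]


class DrawingSchemaError(ValueError):
    """A serialized drawing record violates the stroke-JSON schema."""


@dataclass(frozen=True)
class StrokeDrawing:
    """An ordered sequence of pen strokes on a fixed-size canvas.

    Parameters
    ----------
    task
        Which battery item the drawing answers: ``"cube"``, ``"infinity"``
        or ``"clock"``.
    canvas_width, canvas_height
        Canvas dimensions in pixels.
    strokes
        Ordered strokes; each stroke is an ordered tuple of ``(x, y, t)``
        points with x/y in pixels and t in milliseconds.
    """

    task: str
    canvas_width: int
    canvas_height: int
    strokes: tuple[tuple[Point, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.canvas_width <= 0 or self.canvas_height <= 0:
            raise ValueError("canvas dimensions must be positive")
        strokes = tuple(tuple((float(x), float(y), float(t)) for x, y, t in s) for s in self.strokes)
        object.__setattr__(self, "strokes", strokes)
        for stroke in strokes:
            if not stroke:
                raise ValueError("strokes may not be empty (omit them instead)")
            last_t = -np.inf
            for x, y, t in stroke:
                if not (0 <= x < self.canvas_width and 0 <= y < self.canvas_height):
                    raise ValueError(f"point ({x}, {y}) outside canvas "
                                     f"{self.canvas_width}x{self.canvas_height}")
                if t < last_t:
                    raise ValueError("timestamps within a stroke must be non-decreasing")
                last_t = t

    @property
    def n_strokes(self) -> int:
        return len(self.strokes)

    def is_empty(self) -> bool:
        return not self.strokes

    def translated(self, dx: float, dy: float) -> "StrokeDrawing":
        """Return a copy with all ink shifted by (dx, dy), clipped to canvas."""
        w, h = self.canvas_width, self.canvas_height
        moved = tuple(
            tuple((min(max(x + dx, 0.0), w - 1e-6), min(max(y + dy, 0.0), h - 1e-6), t)
                  for x, y, t in s)
            for s in self.strokes
        )
        return StrokeDrawing(self.task, w, h, moved)


@dataclass(frozen=True)
class RasterImage:
    """A grayscale intensity grid with values in [0, 1]."""

    pixels: np.ndarray  # (height, width) float array

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PreprocessSpec:
    """How to turn raw strokes into classifier-ready rasters.

    ``out_size`` is the square side of the classifier input; ``margin_fraction``
    is the blank border kept around the ink after rescaling.  ``polarity``
    chooses whether ink is bright (``"ink-high"``) or dark (``"ink-low"``).
    """

    out_size: int = 96
    stroke_thickness: int = 2
    polarity: str = "ink-high"
    margin_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.out_size < 16:
            raise ValueError("out_size must be at least 16 px")
        if self.stroke_thickness < 1:
            raise ValueError("stroke_thickness must be at least 1 px")
        if self.polarity not in ("ink-high", "ink-low"):
            raise ValueError("polarity must be 'ink-high' or 'ink-low'")
        if not (0.0 <= self.margin_fraction < 0.5):
            raise ValueError("margin_fraction must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# Serialization: {"task": ..., "canvas": {"w":, "h":}, "strokes": [[[x,y,t]...]...]}
# ---------------------------------------------------------------------------

def drawing_to_dict(drawing: StrokeDrawing) -> dict:
    return {
        "task": drawing.task,
        "canvas": {"w": drawing.canvas_width, "h": drawing.canvas_height},
        "strokes": [[[x, y, t] for x, y, t in s] for s in drawing.strokes],
    }


def drawing_from_dict(record: dict) -> StrokeDrawing:
    for key in ("task", "canvas", "strokes"):
        if key not in record:
            raise DrawingSchemaError(f"drawing record is missing required key {key!r}")
    canvas = record["canvas"]
    for key in ("w", "h"):
        if not isinstance(canvas, dict) or key not in canvas:
            raise DrawingSchemaError(f"drawing record 'canvas' is missing key {key!r}")
    try:
        strokes = tuple(tuple((p[0], p[1], p[2]) for p in s) for s in record["strokes"])
    except (TypeError, IndexError) as exc:
        raise DrawingSchemaError(f"malformed 'strokes' entry: {exc}") from exc
    return StrokeDrawing(record["task"], int(canvas["w"]), int(canvas["h"]), strokes)


def write_drawing(drawing: StrokeDrawing, destination: Union[str, Path, IO[str]]) -> None:
    """Write one drawing as a JSON document (one drawing per file)."""
    doc = json.dumps(drawing_to_dict(drawing))
    if hasattr(destination, "write"):
        destination.write(doc)
    else:
        Path(destination).write_text(doc)


def read_drawing(source: Union[str, Path, IO[str]]) -> StrokeDrawing:
    """Read a drawing written by :func:`write_drawing`.

    Raises :class:`DrawingSchemaError` naming the offending key on malformed
    records.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    try:
        record = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DrawingSchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(record, dict):
        raise DrawingSchemaError("drawing record must be a JSON object")
    return drawing_from_dict(record)


# ---------------------------------------------------------------------------
# Rasterization & preprocessing
# ---------------------------------------------------------------------------

def rasterize(drawing: StrokeDrawing, spec: PreprocessSpec = PreprocessSpec()) -> RasterImage:
    """Render strokes as connected line segments of the given thickness.

    Output dimensions equal the canvas dimensions; ink is 1.0 on a 0.0
    background (polarity is applied later, by :func:`preprocess`).  Rendering
    is deterministic.
    """
    img = Image.new("L", (drawing.canvas_width, drawing.canvas_height), 0)
    draw = ImageDraw.Draw(img)
    r = spec.stroke_thickness / 2.0
    for stroke in drawing.strokes:
        xy = [(x, y) for x, y, _ in stroke]
        if len(xy) == 1:
            x, y = xy[0]
            draw.ellipse([x - r, y - r, x + r, y + r], fill=255)
        else:
            draw.line(xy, fill=255, width=spec.stroke_thickness, joint="curve")
            # round caps so thick strokes do not end square
            if spec.stroke_thickness > 1:
                for x, y in (xy[0], xy[-1]):
                    draw.ellipse([x - r, y - r, x + r, y + r], fill=255)
    return RasterImage(np.asarray(img, dtype=np.float64) / 255.0)


def ink_bounding_box(raster: RasterImage, threshold: float = 0.0) -> tuple[int, int, int, int] | None:
    """(row0, col0, row1, col1) inclusive bounds of above-threshold pixels, or None."""
    mask = raster.pixels > threshold
    if not mask.any():
        return None
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1])


def preprocess(raster: RasterImage, spec: PreprocessSpec = PreprocessSpec()) -> RasterImage:
    """Center and rescale the ink into a square classifier input.

    The ink bounding box is scaled (aspect preserved) to fit ``out_size``
    minus margins and pasted centered; intensities stay in [0, 1] and the
    requested polarity is applied.  An all-blank input yields an all-background
    grid of the target size.
    """
    n = spec.out_size
    bbox = ink_bounding_box(raster)
    if bbox is None:
        out = np.zeros((n, n))
        return RasterImage(out if spec.polarity == "ink-high" else 1.0 - out)

    r0, c0, r1, c1 = bbox
    crop = raster.pixels[r0:r1 + 1, c0:c1 + 1]
    inner = max(int(round(n * (1.0 - 2.0 * spec.margin_fraction))), 1)
    scale = min(inner / crop.shape[0], inner / crop.shape[1])
    new_h = max(int(round(crop.shape[0] * scale)), 1)
    new_w = max(int(round(crop.shape[1] * scale)), 1)
    img = Image.fromarray(np.uint8(np.clip(crop, 0, 1) * 255))
    img = img.resize((new_w, new_h), Image.BILINEAR)
    resized = np.asarray(img, dtype=np.float64) / 255.0

    out = np.zeros((n, n))
    top = (n - new_h) // 2
    left = (n - new_w) // 2
    out[top:top + new_h, left:left + new_w] = resized
    if spec.polarity == "ink-low":
        out = 1.0 - out
    return RasterImage(out)


def drawing_to_input(drawing: StrokeDrawing, spec: PreprocessSpec = PreprocessSpec()) -> RasterImage:
    """Rasterize then preprocess: the full stroke-record -> classifier-input path."""
    return preprocess(rasterize(drawing, spec), spec)


def save_raster_png(raster: RasterImage, path: Union[str, Path]) -> None:
    Image.fromarray(np.uint8(np.clip(raster.pixels, 0, 1) * 255)).save(path, format="PNG")


def load_raster_png(path: Union[str, Path]) -> RasterImage:
    img = Image.open(path).convert("L")
    return RasterImage(np.asarray(img, dtype=np.float64) / 255.0)
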