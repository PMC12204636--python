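"""Synthetic labeled drawings for the three battery tasks.

Real patient drawings are unavailable, so the classifier trains and is
evaluated on parametric synthetic sketches: a wireframe cube in oblique
projection, two overlapping figure-eight (lemniscate) curves, and a clock face
showing ten past five.  Each generator starts from a canonical template on a
256x256 canvas and applies impairment-like distortions — vertex jitter, stroke
dropping, sinusoidal wobble, hand/numeral errors, curve-closure gaps.

Ground-truth correctness is defined by generator-side geometric checks
(edge-endpoint matching for the cube, closure + mutual intersection for the
infinities, circle/numeral/hand configuration for the clock).  The thresholds
are the module-level ``*_TOL`` constants below.  A drawing is labeled correct
only if it passes every check for its task; incorrect drawings fail at least
one.  Clock correctness is all-or-nothing, matching the single point award of
the scoring rubric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import LineString

from .drawing import Point, StrokeDrawing, TASKS

CANVAS = 256

# --- correctness-rubric constants (documented thresholds) -------------------
CLOSURE_TOL = 6.0        # px: max endpoint gap for a curve to count as closed
CUBE_VERTEX_TOL = 10.0   # px: max endpoint distance from a canonical cube vertex
CLOCK_ANGLE_TOL = 15.0   # deg: numeral angular tolerance around its k*30 slot
CLOCK_HAND_TOL = 20.0    # deg: hand angular tolerance around the 5:10 layout
CLOCK_RADIAL_CV = 0.15   # max radial coefficient of variation for the face circle
NUMERAL_MAX_DIAG = 26.0  # px: numeral glyphs must stay small
HAND_BASE_TOL = 16.0     # px: hands must start near the clock center

_HAND_ANGLES = {"hour": (5 + 10 / 60) * 30.0, "minute": 10 / 60 * 360.0}  # deg from 12, clockwise
_POINT_DT = 8.0  # ms between successive synthetic pen points


@dataclass(frozen=True)
class DistortionSpec:
    """Parametric impairment-like distortions applied to a template drawing."""

    vertex_jitter_sd: float = 0.0     # px
    stroke_drop_prob: float = 0.0     # probability per stroke
    wobble_amplitude: float = 0.0     # px, sinusoidal perpendicular displacement
    wobble_frequency: float = 2.0     # cycles per stroke
    clock_hand_error: str = "none"    # none | wrong-time | missing-hand
    clock_numeral_errors: int = 0     # numerals removed or relocated, 0..12
    closure_gap: float = 0.0          # px trimmed so closed curves end open

    def __post_init__(self) -> None:
        if not (0.0 <= self.stroke_drop_prob <= 1.0):
            raise ValueError("stroke_drop_prob must lie in [0, 1]")
        for name in ("vertex_jitter_sd", "wobble_amplitude", "closure_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.clock_hand_error not in ("none", "wrong-time", "missing-hand"):
            raise ValueError("clock_hand_error must be none|wrong-time|missing-hand")
        if not (0 <= self.clock_numeral_errors <= 12):
            raise ValueError("clock_numeral_errors must lie in 0..12")


@dataclass(frozen=True)
class SynthLabel:
    task: str
    correct: bool
    distortion: DistortionSpec
    seed: int


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _clip(points: np.ndarray) -> np.ndarray:
    return np.clip(points, 0.0, CANVAS - 1e-3)

def _stroke(points: np.ndarray, t0: float = 0.0) -> tuple[Point, ...]:
    points = _clip(np.asarray(points, dtype=float))
    return tuple((float(x), float(y), t0 + i * _POINT_DT) for i, (x, y) in enumerate(points))


def _polyline(p0: np.ndarray, p1: np.ndarray, n: int = 9) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return p0[None, :] * (1 - t) + p1[None, :] * t


def _wobble(points: np.ndarray, amplitude: float, frequency: float,
            phase: float, pin_ends: bool = True) -> np.ndarray:
    """Sinusoidal displacement perpendicular to the local direction of travel."""
    if amplitude <= 0 or len(points) < 3:
        return points
    d = np.gradient(points, axis=0)
    norms = np.hypot(d[:, 0], d[:, 1])
    norms[norms == 0] = 1.0
    normal = np.stack([-d[:, 1], d[:, 0]], axis=1) / norms[:, None]
    s = np.linspace(0.0, 1.0, len(points))
    wave = amplitude * np.sin(2 * math.pi * frequency * s + phase)
    if pin_ends:
        wave *= np.sin(math.pi * s)  # taper so endpoints stay put
    return points + normal * wave[:, None]


def _apply_gap(points: np.ndarray, gap: float) -> np.ndarray:
    """Trim arc length ``gap`` from the end of a closed polyline, opening it."""
    if gap <= 0:
        return points
    seg = np.hypot(*np.diff(points, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg[::-1])])
    keep = len(points) - int(np.searchsorted(cum, gap))
    return points[:max(keep, 2)]


def _endpoint_gap(stroke: Sequence[Point]) -> float:
    (x0, y0, _), (x1, y1, _) = stroke[0], stroke[-1]
    return math.hypot(x1 - x0, y1 - y0)


def _stroke_xy(stroke: Sequence[Point]) -> np.ndarray:
    return np.array([(x, y) for x, y, _ in stroke])


# ---------------------------------------------------------------------------
# cube
# ---------------------------------------------------------------------------

_CUBE_FRONT = np.array([[64, 96], [160, 96], [160, 192], [64, 192]], dtype=float)
_CUBE_OFFSET = np.array([40.0, -32.0])

def cube_template_vertices() -> np.ndarray:
    """The 8 canonical vertices: front square then depth-offset back square."""
    return np.vstack([_CUBE_FRONT, _CUBE_FRONT + _CUBE_OFFSET])

#: The 12 edges as index pairs into :func:`cube_template_vertices`.
CUBE_EDGES: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 2), (2, 3), (3, 0),          # front square
    (4, 5), (5, 6), (6, 7), (7, 4),          # back square
    (0, 4), (1, 5), (2, 6), (3, 7),          # connectors
)


def generate_cube(distortion: DistortionSpec = DistortionSpec(), seed: int = 0) -> StrokeDrawing:
    """A 12-edge wireframe cube in oblique projection, perturbed per spec."""
    rng = np.random.default_rng(seed)
    vertices = cube_template_vertices()
    if distortion.vertex_jitter_sd > 0:
        vertices = vertices + rng.normal(0, distortion.vertex_jitter_sd, vertices.shape)
    drops = rng.random(len(CUBE_EDGES)) < distortion.stroke_drop_prob
    phases = rng.uniform(0, 2 * math.pi, len(CUBE_EDGES))
    strokes = []
    t0 = 0.0
    for k, (i, j) in enumerate(CUBE_EDGES):
        if drops[k]:
            continue
        pts = _polyline(vertices[i], vertices[j])
        pts = _wobble(pts, distortion.wobble_amplitude, distortion.wobble_frequency, phases[k])
        if distortion.closure_gap > 0:
            pts = _apply_gap(pts, distortion.closure_gap)
        strokes.append(_stroke(pts, t0))
        t0 += len(pts) * _POINT_DT + 100.0
    return StrokeDrawing("cube", CANVAS, CANVAS, tuple(strokes))


def check_cube(drawing: StrokeDrawing) -> bool:
    """All 12 edges present, endpoints near their canonical vertices."""
    if drawing.n_strokes != 12:
        return False
    vertices = cube_template_vertices()
    unmatched = set(range(12))
    for stroke in drawing.strokes:
        ends = _stroke_xy(stroke)[[0, -1]]
        hit = None
        for k in unmatched:
            i, j = CUBE_EDGES[k]
            d_fwd = max(np.linalg.norm(ends[0] - vertices[i]), np.linalg.norm(ends[1] - vertices[j]))
            d_rev = max(np.linalg.norm(ends[0] - vertices[j]), np.linalg.norm(ends[1] - vertices[i]))
            if min(d_fwd, d_rev) <= CUBE_VERTEX_TOL:
                hit = k
                break
        if hit is None:
            return False
        unmatched.discard(hit)
    return not unmatched


# ---------------------------------------------------------------------------
# overlapping infinities (lemniscates)
# ---------------------------------------------------------------------------

def _lemniscate(center: np.ndarray, half_width: float, n: int = 72) -> np.ndarray:
    t = np.linspace(0, 2 * math.pi, n)
    denom = 1 + np.sin(t) ** 2
    x = half_width * np.cos(t) / denom
    y = 0.6 * half_width * np.sin(t) * np.cos(t) / denom
    pts = np.stack([x, y], axis=1) + center[None, :]
    pts[-1] = pts[0]  # numerically exact closure
    return pts

_INF_CENTERS = (np.array([100.0, 128.0]), np.array([156.0, 128.0]))
_INF_HALF_WIDTH = 58.0


def generate_infinity(distortion: DistortionSpec = DistortionSpec(), seed: int = 0) -> StrokeDrawing:
    """Two overlapping figure-eight curves sampled as closed polylines.

    Vertex jitter shifts each curve's center and scales it, so heavy jitter
    separates the curves instead of merely roughening them.
    """
    rng = np.random.default_rng(seed)
    strokes = []
    t0 = 0.0
    for center in _INF_CENTERS:
        c = center + rng.normal(0, distortion.vertex_jitter_sd, 2)
        scale = math.exp(rng.normal(0, distortion.vertex_jitter_sd / 80.0)) if distortion.vertex_jitter_sd else 1.0
        pts = _lemniscate(c, _INF_HALF_WIDTH * scale)
        pts = _wobble(pts, distortion.wobble_amplitude, distortion.wobble_frequency,
                      rng.uniform(0, 2 * math.pi))
        pts = _apply_gap(pts, distortion.closure_gap)
        if rng.random() < distortion.stroke_drop_prob:
            continue
        strokes.append(_stroke(pts, t0))
        t0 += len(pts) * _POINT_DT + 100.0
    return StrokeDrawing("infinity", CANVAS, CANVAS, tuple(strokes))


def check_infinity(drawing: StrokeDrawing) -> bool:
    """Two closed curves whose point sets intersect."""
    if drawing.n_strokes != 2:
        return False
    if any(_endpoint_gap(s) > CLOSURE_TOL for s in drawing.strokes):
        return False
    a, b = (LineString(_stroke_xy(s)) for s in drawing.strokes)
    return bool(a.intersects(b))


# ---------------------------------------------------------------------------
# clock at ten past five
# ---------------------------------------------------------------------------

_CLOCK_CENTER = np.array([128.0, 128.0])
_CLOCK_R = 86.0
_NUMERAL_R = 0.80 * _CLOCK_R
_HAND_LEN = {"hour": 0.45 * _CLOCK_R, "minute": 0.72 * _CLOCK_R}


def _clock_dir(angle_deg: float) -> np.ndarray:
    """Unit vector for an angle measured clockwise from 12 o'clock (y down)."""
    rad = math.radians(angle_deg - 90.0)
    return np.array([math.cos(rad), math.sin(rad)])


def numeral_position(k: int) -> np.ndarray:
    """Canonical center of numeral k (1..12) on the template face."""
    return _CLOCK_CENTER + _NUMERAL_R * _clock_dir(k * 30.0)


def _numeral_glyph(center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A small zigzag glyph standing in for a digit; ~8 px tall."""
    z = np.array([[-3, -4], [1, -4], [-2, 1], [2, 4], [-3, 4]], dtype=float)
    rot = rng.uniform(-0.3, 0.3)
    c, s = math.cos(rot), math.sin(rot)
    return z @ np.array([[c, -s], [s, c]]).T + center[None, :]


def generate_clock(distortion: DistortionSpec = DistortionSpec(), seed: int = 0) -> StrokeDrawing:
    """Clock face: circle, numerals 1-12, hour hand toward ~5:10, minute toward 2."""
    rng = np.random.default_rng(seed)
    jit = distortion.vertex_jitter_sd
    strokes: list[tuple[Point, ...]] = []
    t0 = 0.0

    def emit(pts: np.ndarray) -> None:
        nonlocal t0
        if rng.random() < distortion.stroke_drop_prob:
            return
        strokes.append(_stroke(pts, t0))
        t0 += len(pts) * _POINT_DT + 80.0

    # face circle
    center = _CLOCK_CENTER + rng.normal(0, jit, 2)
    theta = np.linspace(0, 2 * math.pi, 90)
    circle = center[None, :] + _CLOCK_R * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    circle[-1] = circle[0]
    circle = _wobble(circle, distortion.wobble_amplitude, distortion.wobble_frequency,
                     rng.uniform(0, 2 * math.pi))
    circle = _apply_gap(circle, distortion.closure_gap)
    emit(circle)

    # numerals, with the first `clock_numeral_errors` slots corrupted
    corrupt = set(rng.choice(12, size=distortion.clock_numeral_errors, replace=False).tolist())
    for idx, k in enumerate(range(1, 13)):
        pos = numeral_position(k) + rng.normal(0, jit, 2)
        if idx in corrupt:
            if rng.random() < 0.5:
                continue  # numeral omitted
            pos = center + rng.uniform(0.2, 1.1) * _CLOCK_R * _clock_dir(rng.uniform(0, 360))
        emit(_numeral_glyph(pos, rng))

    # hands
    for hand, angle in _HAND_ANGLES.items():
        if distortion.clock_hand_error == "missing-hand" and hand == "hour":
            continue
        if distortion.clock_hand_error == "wrong-time":
            angle = (angle + rng.uniform(60.0, 300.0)) % 360.0
        angle += rng.normal(0, jit)
        tip = center + _HAND_LEN[hand] * _clock_dir(angle)
        emit(_polyline(center, tip, n=6))

    return StrokeDrawing("clock", CANVAS, CANVAS, tuple(strokes))


def _angle_of(vec: np.ndarray) -> float:
    """Clockwise-from-12 angle of a vector in screen coordinates, degrees."""
    return (math.degrees(math.atan2(vec[1], vec[0])) + 90.0) % 360.0


def _angdiff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def check_clock(drawing: StrokeDrawing) -> bool:
    """Closed round face, all 12 numerals in their slots, both hands at ~5:10."""
    if drawing.is_empty():
        return False
    # face: the stroke with the largest bounding box
    def diag(s):
        xy = _stroke_xy(s)
        return float(np.linalg.norm(xy.max(0) - xy.min(0)))
    face = max(drawing.strokes, key=diag)
    if _endpoint_gap(face) > CLOSURE_TOL:
        return False
    xy = _stroke_xy(face)
    center = xy.mean(axis=0)
    radii = np.hypot(*(xy - center).T)
    if radii.mean() < 20 or radii.std() / radii.mean() > CLOCK_RADIAL_CV:
        return False

    slots_found: set[int] = set()
    hands_found: set[str] = set()
    for stroke in drawing.strokes:
        if stroke is face:
            continue
        sxy = _stroke_xy(stroke)
        d = float(np.linalg.norm(sxy.max(0) - sxy.min(0)))
        if d <= NUMERAL_MAX_DIAG:  # candidate numeral
            c = sxy.mean(axis=0)
            r = float(np.linalg.norm(c - center))
            if not (0.6 * radii.mean() <= r <= 0.95 * radii.mean()):
                continue
            ang = _angle_of(c - center)
            for k in range(1, 13):
                if _angdiff(ang, k * 30.0) <= CLOCK_ANGLE_TOL:
                    slots_found.add(k)
                    break
        else:  # candidate hand
            ends = sxy[[0, -1]]
            d_to_center = np.linalg.norm(ends - center, axis=1)
            base, tip = (ends[0], ends[1]) if d_to_center[0] < d_to_center[1] else (ends[1], ends[0])
            if np.linalg.norm(base - center) > HAND_BASE_TOL:
                continue
            ang = _angle_of(tip - base)
            for hand, target in _HAND_ANGLES.items():
                if _angdiff(ang, target) <= CLOCK_HAND_TOL:
                    hands_found.add(hand)
    return slots_found == set(range(1, 13)) and hands_found == {"hour", "minute"}


# ---------------------------------------------------------------------------
# labeling and dataset assembly
# ---------------------------------------------------------------------------

_CHECKS = {"cube": check_cube, "infinity": check_infinity, "clock": check_clock}
_GENERATORS = {"cube": generate_cube, "infinity": generate_infinity, "clock": generate_clock}


def drawing_is_correct(drawing: StrokeDrawing) -> bool:
    """Apply the generator-side correctness rubric for the drawing's task."""
    return _CHECKS[drawing.task](drawing)


#: Distortion used for drawings labeled correct: mild tremor only.
CORRECT_DISTORTION = DistortionSpec(vertex_jitter_sd=1.5, wobble_amplitude=1.2,
                                    wobble_frequency=2.5)

#: Failure modes per task; one is picked at random for each incorrect drawing.
INCORRECT_MODES: dict[str, tuple[DistortionSpec, ...]] = {
    "cube": (
        DistortionSpec(vertex_jitter_sd=18.0, wobble_amplitude=1.2),
        DistortionSpec(vertex_jitter_sd=1.5, stroke_drop_prob=0.35),
        DistortionSpec(vertex_jitter_sd=1.5, closure_gap=22.0),
    ),
    "infinity": (
        DistortionSpec(vertex_jitter_sd=45.0, wobble_amplitude=1.2),
        DistortionSpec(vertex_jitter_sd=1.5, stroke_drop_prob=0.6),
        DistortionSpec(vertex_jitter_sd=1.5, closure_gap=28.0),
    ),
    "clock": (
        DistortionSpec(vertex_jitter_sd=1.5, clock_hand_error="missing-hand"),
        DistortionSpec(vertex_jitter_sd=1.5, clock_hand_error="wrong-time"),
        DistortionSpec(vertex_jitter_sd=1.5, clock_numeral_errors=6),
        DistortionSpec(vertex_jitter_sd=1.5, stroke_drop_prob=0.3),
        DistortionSpec(vertex_jitter_sd=14.0, wobble_amplitude=4.0),
    ),
}

_MAX_RESAMPLE = 40


def generate_labeled(task: str, correct: bool, seed: int) -> tuple[StrokeDrawing, SynthLabel]:
    """One drawing whose rubric verdict is guaranteed to match ``correct``.

    Distortion parameters are drawn from :data:`CORRECT_DISTORTION` or a
    random entry of :data:`INCORRECT_MODES`; the candidate is re-drawn (new
    sub-seed) until the rubric verdict matches, which terminates quickly
    because the modes sit far from the rubric thresholds.
    """
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_RESAMPLE):
        if correct:
            spec = CORRECT_DISTORTION
        else:
            modes = INCORRECT_MODES[task]
            spec = modes[rng.integers(len(modes))]
        sub_seed = int(rng.integers(2 ** 31))
        d = _GENERATORS[task](spec, sub_seed)
        if drawing_is_correct(d) == correct:
            return d, SynthLabel(task, correct, spec, sub_seed)
    raise RuntimeError(f"could not generate a {'correct' if correct else 'incorrect'} "
                       f"{task} drawing in {_MAX_RESAMPLE} attempts")


def generate_labeled_dataset(n_per_cell: int, correct_fraction: float = 0.5,
                             seed: int = 0) -> list[tuple[StrokeDrawing, SynthLabel]]:
    """For each task, ``n_per_cell`` drawings with the requested correct fraction.

    Deterministic per seed.  ``round(n_per_cell * correct_fraction)`` drawings
    per task are correct, the rest incorrect; order is correct-first within
    each task block (shuffle downstream if needed).
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be at least 1")
    if not (0.0 <= correct_fraction <= 1.0):
        raise ValueError("correct_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[tuple[StrokeDrawing, SynthLabel]] = []
    for task in TASKS:
        n_correct = int(round(n_per_cell * correct_fraction))
        for i in range(n_per_cell):
            out.append(generate_labeled(task, i < n_correct, int(rng.integers(2 ** 31))))
    return out
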