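"""Neck Functional Holistic Analysis Score (NFHAS).

The NFHAS condenses the six age-normalized cervical ROMs (flexion,
extension, left/right lateral bending, left/right rotation) into a single
percentage. The two directions of each movement pair are combined into one
axis value, the three axis values are placed as vertices on mutually
orthogonal axes, the polygon spanned by the vertices is measured with
Heron's formula, and the area is expressed relative to the area of the
ideal polygon in which every normalized ROM equals 100 %.

Severity staging partitions scores into five ordered types: type 1 means
complete ROM, type 5 severe limitation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "MOVEMENTS",
    "NfhasResult",
    "vertex_distance",
    "heron_area",
    "nfhas_score",
    "stage_severity",
]

#: Canonical movement order used throughout the package.
MOVEMENTS = ("F", "E", "Llb", "Rlb", "Lrt", "Rrt")

#: Movement pairs forming the three anatomical axes.
AXIS_PAIRS = (("F", "E"), ("Llb", "Rlb"), ("Lrt", "Rrt"))

#: Default staging cut points on the score (equal-width bands).
DEFAULT_STAGE_THRESHOLDS = (80.0, 60.0, 40.0, 20.0)

_TRIANGLE_TOL = 1e-9


class InvalidGeometryError(ValueError):
    """Side lengths that cannot form a (possibly degenerate) triangle."""


@dataclass(frozen=True)
class NfhasResult:
    """Score (percent of the ideal polygon area) and severity type 1-5."""

    score: float
    severity_type: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("NFHAS score must be non-negative")
        if self.severity_type not in (1, 2, 3, 4, 5):
            raise ValueError("severity type must be in 1..5")


def vertex_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance between two ROM vertices in 3-D."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (3,) or q.shape != (3,):
        raise ValueError("vertices must be 3-D points")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("vertex coordinates must be finite")
    return float(np.linalg.norm(p - q))


def heron_area(a: float, b: float, c: float) -> float:
    """Triangle area from its three side lengths.

    A = sqrt(s(s-a)(s-b)(s-c)) with s the semiperimeter.  A tiny negative
    radicand from floating-point cancellation is clamped to zero; a genuine
    triangle-inequality violation raises :class:`InvalidGeometryError`.
    """
    if a < 0 or b < 0 or c < 0:
        raise InvalidGeometryError("side lengths must be non-negative")
    s = (a + b + c) / 2.0
    scale = max(a, b, c, 1.0)
    for side in (a, b, c):
        if side > s + _TRIANGLE_TOL * scale:
            raise InvalidGeometryError(
                f"triangle inequality violated: side {side} exceeds semiperimeter {s}"
            )
    radicand = s * (s - a) * (s - b) * (s - c)
    if radicand < 0.0:
        radicand = 0.0
    return math.sqrt(radicand)


def _axis_values(
    normalized_roms: Sequence[float], combine: Literal["mean", "sum"]
) -> np.ndarray:
    roms = np.asarray(normalized_roms, dtype=float)
    if roms.shape != (6,):
        raise ValueError("expected six normalized ROM values (F, E, Llb, Rlb, Lrt, Rrt)")
    if not np.isfinite(roms).all():
        raise ValueError("normalized ROMs must be finite")
    if (roms < 0).any():
        raise ValueError("normalized ROMs must be non-negative")
    pairs = roms.reshape(3, 2)
    if combine == "mean":
        return pairs.mean(axis=1)
    if combine == "sum":
        return pairs.sum(axis=1)
    raise ValueError(f"unknown axis combination {combine!r}")


def _triangle_area_on_axes(axes: np.ndarray) -> float:
    """Area of the triangle with vertices (a,0,0), (0,b,0), (0,0,c)."""
    a_fe, a_lb, a_rt = axes
    v = [
        np.array([a_fe, 0.0, 0.0]),
        np.array([0.0, a_lb, 0.0]),
        np.array([0.0, 0.0, a_rt]),
    ]
    sides = (
        vertex_distance(v[0], v[1]),
        vertex_distance(v[1], v[2]),
        vertex_distance(v[2], v[0]),
    )
    return heron_area(*sides)


def _octant_area(roms: np.ndarray) -> float:
    """Summed area of the eight octant faces of the six-vertex polyhedron.

    Each movement direction is a vertex on its own half-axis; every octant
    contributes one triangular face joining one vertex per axis.
    """
    fe = (roms[0], roms[1])  # +x, -x
    lb = (roms[2], roms[3])  # +y, -y
    rt = (roms[4], roms[5])  # +z, -z
    total = 0.0
    for sx, x in zip((1.0, -1.0), fe):
        for sy, y in zip((1.0, -1.0), lb):
            for sz, z in zip((1.0, -1.0), rt):
                vx = np.array([sx * x, 0.0, 0.0])
                vy = np.array([0.0, sy * y, 0.0])
                vz = np.array([0.0, 0.0, sz * z])
                total += heron_area(
                    vertex_distance(vx, vy),
                    vertex_distance(vy, vz),
                    vertex_distance(vz, vx),
                )
    return total


def nfhas_score(
    normalized_roms: Sequence[float],
    *,
    geometry: Literal["triangle", "octant"] = "triangle",
    combine: Literal["mean", "sum"] = "mean",
) -> float:
    """NFHAS score from the six age-normalized ROMs (percent of normative).

    Parameters
    ----------
    normalized_roms
        Six percentages in the order F, E, Llb, Rlb, Lrt, Rrt.
    geometry
        ``"triangle"`` (default): one triangle with one vertex per axis,
        each axis the combination of its two directions.  ``"octant"``:
        six vertices on the positive/negative half-axes, the eight octant
        faces summed.
    combine
        How the two directions of a pair form the axis value in triangle
        geometry (mean or sum; the ratio to the ideal polygon is identical
        for both since the ideal is combined the same way).

    Returns
    -------
    float
        100 * A / A_ideal, where A_ideal uses 100 % on every ROM.  Scores
        above 100 are possible (hypermobility) and are not clipped.
    """
    roms = np.asarray(normalized_roms, dtype=float)
    if geometry == "triangle":
        axes = _axis_values(roms, combine)
        ideal = _axis_values(np.full(6, 100.0), combine)
        area = _triangle_area_on_axes(axes)
        ideal_area = _triangle_area_on_axes(ideal)
    elif geometry == "octant":
        _axis_values(roms, "mean")  # validation only
        area = _octant_area(roms)
        ideal_area = _octant_area(np.full(6, 100.0))
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return 100.0 * area / ideal_area


def stage_severity(
    scores: Iterable[float],
    *,
    mode: Literal["threshold", "kmeans"] = "threshold",
    thresholds: Sequence[float] = DEFAULT_STAGE_THRESHOLDS,
    seed: int = 0,
) -> np.ndarray:
    """Assign each score a severity type 1 (best) .. 5 (worst).

    ``threshold`` mode bins scores at fixed cut points (defaults 80/60/40/20,
    i.e. equal-width bands; scores above 100 are type 1).  ``kmeans`` mode
    runs 1-D k-means with k=5 and a fixed seed, sorting centroids so the
    highest-score cluster becomes type 1; with fewer than 5 distinct scores
    it falls back to threshold mode with a warning.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("at least one score is required")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")

    if mode == "kmeans":
        if np.unique(scores).size < 5:
            warnings.warn(
                "fewer than 5 distinct scores; falling back to threshold staging",
                stacklevel=2,
            )
            mode = "threshold"
        else:
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=5, n_init=10, random_state=seed)
            labels = km.fit_predict(scores.reshape(-1, 1))
            order = np.argsort(-km.cluster_centers_.ravel())  # descending score
            remap = np.empty(5, dtype=int)
            remap[order] = np.arange(1, 6)
            return remap[labels]

    cuts = np.asarray(thresholds, dtype=float)
    if cuts.shape != (4,) or not np.all(np.diff(cuts) < 0):
        raise ValueError("thresholds must be four strictly decreasing values")
    # score >= cuts[0] -> 1, >= cuts[1] -> 2, ..., below cuts[3] -> 5
    types = 5 - np.searchsorted(np.sort(cuts), scores, side="right")
    return types.astype(int)
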