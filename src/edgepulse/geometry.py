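"""Planar geometry of tracked cells, interfaces and vertices.

Lengths are vertex-to-vertex chords, areas are shoelace polygon areas and
interface orientations are acute angles measured from the embryo's
anterior-posterior (AP) axis, so 0° is an AP-aligned interface and 90° one
aligned with the dorso-ventral (DV) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Edge",
    "JunctionAngles",
    "polygon_area",
    "edge_length",
    "edge_orientation",
    "junction_angles",
]

AP_AXIS = np.array([1.0, 0.0])


@dataclass
class Edge:
    """A cell-cell interface delimited by two vertices (µm).

    ``cells`` maps flanking-cell roles (anterior/posterior/dorsal/ventral)
    to cell ids where known.  Coincident endpoints are allowed: an interface
    fully contracted to a vertex has length 0.
    """

    p1: np.ndarray
    p2: np.ndarray
    cells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        for p in (self.p1, self.p2):
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise ValueError("edge endpoints must be finite 2D points")


@dataclass
class JunctionAngles:
    """Flanking-junction angles at the two ends of an interface (degrees)."""

    theta1: float
    theta2: float

    @property
    def theta_avg(self) -> float:
        return 0.5 * (self.theta1 + self.theta2)


def polygon_area(polygon: np.ndarray) -> float:
    """Absolute shoelace area of an ordered polygon, in µm².

    Orientation-independent: clockwise and counter-clockwise vertex orders
    give the same value.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon needs at least 3 ordered (x, y) vertices")
    x, y = poly[:, 0], poly[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def edge_length(edge: Edge) -> float:
    """Euclidean distance between the two vertices delimiting the interface."""
    return float(np.hypot(*(edge.p2 - edge.p1)))


def edge_orientation(edge: Edge | np.ndarray, ap_axis: np.ndarray = AP_AXIS) -> float:
    """Acute angle (degrees, in [0, 90]) between an interface and the AP axis.

    Accepts an :class:`Edge` or a direction vector.  90° corresponds to the
    DV axis.  Raises for a zero-length interface, whose orientation is
    undefined.
    """
    if isinstance(edge, Edge):
        vec = edge.p2 - edge.p1
    else:
        vec = np.asarray(edge, dtype=float)
    norm = np.hypot(*vec)
    if norm == 0:
        raise ValueError("orientation undefined for a zero-length edge")
    ax = np.asarray(ap_axis, dtype=float)
    ax = ax / np.hypot(*ax)
    cosang = abs(float(np.dot(vec, ax)) / norm)
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def _direction(polyline: np.ndarray, fit_window: float = 1.0) -> np.ndarray:
    """Unit direction of a junction polyline leaving its first point.

    The direction is taken from the polyline chord within ``fit_window`` µm
    of the shared vertex (first point); for a straight first segment this is
    simply that segment's direction.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim == 1:  # a bare direction vector
        vec = pts
    else:
        if pts.shape[0] < 2:
            raise ValueError("junction polyline needs at least two points")
        origin = pts[0]
        # walk along the polyline up to fit_window µm
        target = pts[1]
        acc = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            seg = float(np.hypot(*(b - a)))
            if seg == 0:
                continue
            if acc + seg >= fit_window:
                t = (fit_window - acc) / seg
                target = a + t * (b - a)
                break
            target = b
            acc += seg
        vec = target - origin
    norm = np.hypot(*vec)
    if norm == 0:
        raise ValueError("degenerate (zero-length) junction segment")
    return vec / norm


def junction_angles(
    edge: Edge,
    anterior_pair: tuple[np.ndarray, np.ndarray],
    posterior_pair: tuple[np.ndarray, np.ndarray],
    fit_window: float = 1.0,
) -> JunctionAngles:
    """Angles θ₁, θ₂ between the junction pairs flanking an interface.

    Each pair holds the two junction polylines emanating from one endpoint
    of ``edge`` (first polyline point = the shared vertex), or bare
    direction vectors.  θᵢ is the interior angle between the two junction
    directions, in (0°, 180°]; θ_avg = (θ₁ + θ₂) / 2 is the tension proxy
    used to characterise interface geometry.
    """
    thetas = []
    for pair in (anterior_pair, posterior_pair):
        d1 = _direction(pair[0], fit_window)
        d2 = _direction(pair[1], fit_window)
        cosang = np.clip(float(np.dot(d1, d2)), -1.0, 1.0)
        theta = float(np.degrees(np.arccos(cosang)))
        if theta == 0.0:
            raise ValueError("coincident junction directions give a zero angle")
        thetas.append(theta)
    return JunctionAngles(theta1=thetas[0], theta2=thetas[1])
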