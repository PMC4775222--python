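"""Detection and characterisation of vertex-resolution events.

A multicellular vertex "resolves" when a new cell-cell interface assembles
from it.  Onset is the first time the nascent interface exceeds a length
threshold (1 µm by convention); an event that never sustains a
supra-threshold length for at least the non-resolution window is either
unresolved (never crossed) or collapsed (crossed but fell back).  The new
interface is further characterised by its orientation a fixed delay after
onset and its mean elongation rate over a measurement window:

    rate(t) = (l(t) − l(t₀)) / (t − t₀)

reported in µm/min.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core import EdgeTrace
from .geometry import Edge, edge_orientation

__all__ = [
    "AnalysisConfig",
    "ResolutionStatus",
    "ResolutionEvent",
    "detect_onset",
    "classify_resolution",
    "elongation_rate",
    "resolution_angle",
    "analyze_trace",
]


@dataclass
class AnalysisConfig:
    """Conventions for resolution analysis (all values positive).

    onset_threshold : µm — length that must be strictly exceeded (default 1).
    angle_delay : s — delay after onset at which orientation is read (150).
    sector_halfwidth : degrees — half-width of the AP/DV sectors (30).
    rate_window : s — window for the elongation rate (90).
    nonresolution_window : s — minimum supra-threshold time for an event to
        count as resolved (60).
    """

    onset_threshold: float = 1.0
    angle_delay: float = 150.0
    sector_halfwidth: float = 30.0
    rate_window: float = 90.0
    nonresolution_window: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "onset_threshold",
            "angle_delay",
            "sector_halfwidth",
            "rate_window",
            "nonresolution_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class ResolutionStatus(str, enum.Enum):
    RESOLVED = "resolved"
    UNRESOLVED = "unresolved"
    COLLAPSED = "collapsed"
    INDETERMINATE = "indeterminate"


@dataclass
class ResolutionEvent:
    """Summary of one interface's resolution behaviour."""

    edge_id: str
    t0: float | None
    status: ResolutionStatus
    orientation_deg: float | None = None
    sector: str | None = None
    elongation_rate: float | None = None  # µm/min
    rate_window: float | None = None  # s


def detect_onset(trace: EdgeTrace, cfg: AnalysisConfig | None = None) -> float | None:
    """Earliest sample time at which l(t) strictly exceeds the threshold.

    Returns ``None`` when the interface never exceeds it ("exceeded" is
    read strictly, so a length exactly at threshold does not trigger).
    """
    cfg = cfg or AnalysisConfig()
    above = trace.lengths > cfg.onset_threshold
    if not np.any(above):
        return None
    return float(trace.times[int(np.argmax(above))])


def _runs_above(trace: EdgeTrace, threshold: float) -> list[tuple[int, int]]:
    """Maximal index runs [i, j] with lengths strictly above threshold."""
    above = trace.lengths > threshold
    runs = []
    i = 0
    n = above.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def classify_resolution(trace: EdgeTrace, cfg: AnalysisConfig | None = None) -> ResolutionStatus:
    """Classify an interface trace as resolved / unresolved / collapsed.

    Resolved: some supra-threshold run spans at least the non-resolution
    window.  Unresolved: the length never exceeds the threshold.
    Collapsed: the interface crossed the threshold but every run fell back
    below it in less than the window.  A trailing run cut short by the end
    of the recording cannot be judged and yields ``INDETERMINATE``.
    """
    cfg = cfg or AnalysisConfig()
    runs = _runs_above(trace, cfg.onset_threshold)
    if not runs:
        return ResolutionStatus.UNRESOLVED
    dt = trace.dt
    spans = [(j - i) * dt for i, j in runs]
    if any(s >= cfg.nonresolution_window for s in spans):
        return ResolutionStatus.RESOLVED
    last_i, last_j = runs[-1]
    if last_j == trace.lengths.size - 1:
        # still above threshold when the recording ends
        return ResolutionStatus.INDETERMINATE
    return ResolutionStatus.COLLAPSED


def _index_at(trace: EdgeTrace, t: float) -> int:
    """Index of the frame nearest to time t; ties go to the earlier frame."""
    d = np.abs(trace.times - t)
    best = np.min(d)
    return int(np.flatnonzero(np.isclose(d, best))[0])


def elongation_rate(trace: EdgeTrace, t0: float, window: float) -> float:
    """Mean elongation rate (l(t₀+window) − l(t₀)) / window, in µm/min.

    Negative rates (net shortening over the window) are allowed.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t_end = t0 + window
    if t_end > trace.times[-1] + 1e-9:
        raise ValueError(
            f"window ends at {t_end:g} s but the trace only spans "
            f"[{trace.times[0]:g}, {trace.times[-1]:g}] s"
        )
    i0 = _index_at(trace, t0)
    i1 = _index_at(trace, t_end)
    dl = trace.lengths[i1] - trace.lengths[i0]
    return float(dl / (window / 60.0))


def resolution_angle(
    trace: EdgeTrace, t0: float, cfg: AnalysisConfig | None = None
) -> tuple[float, str]:
    """Interface orientation ``angle_delay`` seconds after onset.

    Returns (angle in degrees from the AP axis, sector label).  The frame
    nearest t₀ + delay is used (ties to the earlier frame).  Sector is
    ``"AP"`` for angles within ``sector_halfwidth`` of the AP axis,
    ``"DV"`` within the same half-width of the DV axis, else ``"oblique"``.
    """
    cfg = cfg or AnalysisConfig()
    if trace.endpoints is None:
        raise ValueError("trace carries no endpoint coordinates")
    t_meas = t0 + cfg.angle_delay
    if t_meas > trace.times[-1] + 1e-9:
        raise ValueError(
            f"angle is read at {t_meas:g} s but the trace ends at {trace.times[-1]:g} s"
        )
    i = _index_at(trace, t_meas)
    p1, p2 = trace.endpoints[i]
    angle = edge_orientation(Edge(p1, p2))
    if angle <= cfg.sector_halfwidth:
        sector = "AP"
    elif angle >= 90.0 - cfg.sector_halfwidth:
        sector = "DV"
    else:
        sector = "oblique"
    return angle, sector


def analyze_trace(trace: EdgeTrace, cfg: AnalysisConfig | None = None) -> ResolutionEvent:
    """Run the full per-interface analysis: onset, status, angle, rate."""
    cfg = cfg or AnalysisConfig()
    t0 = detect_onset(trace, cfg)
    status = classify_resolution(trace, cfg)
    event = ResolutionEvent(edge_id=trace.edge_id, t0=t0, status=status)
    if t0 is None:
        return event
    if trace.endpoints is not None and t0 + cfg.angle_delay <= trace.times[-1] + 1e-9:
        event.orientation_deg, event.sector = resolution_angle(trace, t0, cfg)
    if t0 + cfg.rate_window <= trace.times[-1] + 1e-9:
        event.elongation_rate = elongation_rate(trace, t0, cfg.rate_window)
        event.rate_window = cfg.rate_window
    return event
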