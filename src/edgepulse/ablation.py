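"""Laser-ablation recoil velocimetry.

Severing a junction under tension releases the two flanking tricellular
vertices, which recoil at a speed proportional to the tension the junction
sustained (assuming uniform viscoelastic properties).  The instantaneous
retraction velocity is estimated from a single interval: the change in
vertex-to-vertex separation between the last pre-ablation frame and the
first post-ablation frame, divided by the time that interval spans — the
ablation exposure plus the acquisition of one image stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import corr_significance

__all__ = ["AblationEvent", "retraction_velocity", "cohort_correlations"]

EDGE_CLASSES = ("control_DV", "new_DV", "AP")


@dataclass
class AblationEvent:
    """One interface ablation: vertex positions and timing (µm, s)."""

    edge_id: str
    pre1: np.ndarray
    pre2: np.ndarray
    post1: np.ndarray | None
    post2: np.ndarray | None
    t_ablation: float
    t_acquisition: float
    edge_class: str = "new_DV"
    theta1: float | None = None
    theta2: float | None = None

    def __post_init__(self) -> None:
        self.pre1 = np.asarray(self.pre1, dtype=float)
        self.pre2 = np.asarray(self.pre2, dtype=float)
        if self.post1 is not None:
            self.post1 = np.asarray(self.post1, dtype=float)
        if self.post2 is not None:
            self.post2 = np.asarray(self.post2, dtype=float)
        if self.t_ablation + self.t_acquisition <= 0:
            raise ValueError("t_ablation + t_acquisition must be positive")
        if self.edge_class not in EDGE_CLASSES:
            raise ValueError(f"edge_class must be one of {EDGE_CLASSES}")

    @property
    def pre_length(self) -> float:
        return float(np.hypot(*(self.pre2 - self.pre1)))

    @property
    def post_length(self) -> float:
        if self.post1 is None or self.post2 is None:
            raise ValueError("missing post-ablation vertex positions")
        return float(np.hypot(*(self.post2 - self.post1)))

    @property
    def theta_avg(self) -> float | None:
        if self.theta1 is None or self.theta2 is None:
            return None
        return 0.5 * (self.theta1 + self.theta2)


def retraction_velocity(event: AblationEvent) -> float:
    """Signed recoil speed in µm/s.

    v = (post-separation − pre-separation) / (t_ablation + t_acquisition).
    Negative when the vertices approach instead of separating.  Invariant
    under rigid motion applied to both frames, since only vertex-to-vertex
    separations enter.
    """
    if event.post1 is None or event.post2 is None:
        raise ValueError(f"event {event.edge_id}: no post-ablation frame")
    return (event.post_length - event.pre_length) / (event.t_ablation + event.t_acquisition)


def cohort_correlations(events: list[AblationEvent]) -> pd.DataFrame:
    """Correlate retraction velocity with junction geometry over a cohort.

    Returns one row per pairing: velocity vs θ_avg over all events carrying
    angles, and velocity vs pre-ablation length within each edge class.
    Pairings with fewer than 3 events or zero variance are kept in the
    table but flagged ``skipped`` with r and p set to NaN.
    """
    velocities = np.array([retraction_velocity(e) for e in events])
    rows = []

    def _pairing(label: str, x: np.ndarray, v: np.ndarray) -> dict:
        row = {"pairing": label, "n": int(x.size), "r": np.nan, "p": np.nan, "flag": ""}
        if x.size < 3:
            row["flag"] = "skipped: fewer than 3 events"
        elif np.ptp(x) == 0 or np.ptp(v) == 0:
            row["flag"] = "skipped: zero variance"
        else:
            r = float(np.corrcoef(x, v)[0, 1])
            row["r"] = r
            row["p"] = corr_significance(r, x.size)
        return row

    has_angle = [i for i, e in enumerate(events) if e.theta_avg is not None]
    thetas = np.array([events[i].theta_avg for i in has_angle])
    rows.append(_pairing("velocity~theta_avg", thetas, velocities[has_angle]))

    for cls in EDGE_CLASSES:
        idx = [i for i, e in enumerate(events) if e.edge_class == cls]
        if not idx:
            continue
        lengths = np.array([events[i].pre_length for i in idx])
        rows.append(_pairing(f"velocity~length[{cls}]", lengths, velocities[idx]))

    return pd.DataFrame(rows)
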