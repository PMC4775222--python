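"""Shared data containers for the junction-dynamics pipeline.

Conventions used throughout the package:

* the image frame has its origin at the top-left corner, with x increasing
  rightward (the embryo's anterior-posterior axis by default) and y
  increasing downward (dorso-ventral axis);
* spatial quantities are micrometres, time is seconds;
* rates of change are reported per minute;
* label images use 0 for boundary/background pixels and positive integers
  for cell identities that are stable across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "EdgeTrace", "TissueTimeSeries"]


@dataclass
class ImageStack:
    """A t/z/channel/y/x raster with physical calibration.

    Parameters
    ----------
    data
        Array with axes ``(t, z, c, y, x)``.  Degenerate axes are kept
        explicit so slicing is unambiguous.
    pixel_size
        Lateral calibration in µm per pixel.
    dt
        Frame interval in seconds.
    channel_names
        One name per channel, e.g. ``["membrane", "myosin"]``.
    apical_high_z
        Whether the apical surface sits at the high end of the z axis.
    """

    data: np.ndarray
    pixel_size: float
    dt: float
    channel_names: list[str] = field(default_factory=lambda: ["membrane"])
    apical_high_z: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"ImageStack.data must have axes (t, z, c, y, x); got ndim={self.data.ndim}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.channel_names) != self.data.shape[2]:
            raise ValueError("channel_names must match the channel axis length")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def frame(self, t: int, channel: int | str = 0, z: int = 0) -> np.ndarray:
        """Return one 2D (y, x) plane."""
        if isinstance(channel, str):
            channel = self.channel_names.index(channel)
        return self.data[t, z, channel]


@dataclass
class EdgeTrace:
    """Length history of one cell-cell interface.

    ``lengths`` is the chord length l(t) between the two vertices that
    delimit the interface.  ``endpoints`` (optional) holds the vertex
    coordinates per frame with shape ``(n, 2, 2)`` ordered
    ``(frame, vertex, xy)``.  ``cells`` maps the flanking-cell roles
    (``anterior``/``posterior``/``dorsal``/``ventral``) to cell ids where
    known.
    """

    edge_id: str
    times: np.ndarray
    lengths: np.ndarray
    endpoints: np.ndarray | None = None
    cells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.size != self.lengths.size:
            raise ValueError("times and lengths must have equal length")
        if self.times.size == 0:
            raise ValueError("empty edge trace")
        if np.any(self.lengths < 0):
            raise ValueError("edge lengths must be non-negative")
        d = np.diff(self.times)
        if d.size and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if self.endpoints is not None:
            self.endpoints = np.asarray(self.endpoints, dtype=float)
            if self.endpoints.shape != (self.times.size, 2, 2):
                raise ValueError("endpoints must have shape (n_frames, 2, 2)")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("dt undefined for a single-sample trace")
        return float(self.times[1] - self.times[0])


@dataclass
class TissueTimeSeries:
    """Tracked cell polygons, areas and (optionally) one central interface.

    ``polygons[cell_id][frame]`` is an ``(k, 2)`` array of ordered boundary
    vertices in µm; ``areas[cell_id]`` the matching per-frame area series.
    """

    times: np.ndarray
    polygons: dict[int, list[np.ndarray]]
    areas: dict[int, np.ndarray]
    edge: EdgeTrace | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.size
        for cid, polys in self.polygons.items():
            if len(polys) != n:
                raise ValueError(f"cell {cid}: polygon list does not span all frames")
        for cid, a in self.areas.items():
            self.areas[cid] = np.asarray(a, dtype=float)
            if self.areas[cid].size != n:
                raise ValueError(f"cell {cid}: area series does not span all frames")

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.polygons)

    @property
    def n_frames(self) -> int:
        return self.times.size

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) over all cells and frames, in µm."""
        pts = np.concatenate([p for polys in self.polygons.values() for p in polys])
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )
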