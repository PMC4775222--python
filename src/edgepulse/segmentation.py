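"""Seeded-watershed segmentation with PIV-based seed tracking.

Cells are delineated in a membrane-reporter image by marker-based
watershed: one seed per cell is expanded until basins meet at the bright
membrane ridges.  Identities are carried across frames by estimating the
local tissue motion with particle image velocimetry (windowed normalized
cross-correlation between consecutive frames) and advecting each seed by
the local displacement before re-running the watershed — manual seeding is
only needed in the first frame.

Seeds and displacement fields live in pixel coordinates; exported polygons
and areas are converted to µm using the stack calibration.  Watershed runs
directly on the (optionally Gaussian-presmoothed) membrane intensity of a
maximum-intensity projection of the most apical slices; a seed with
``cell_id`` 0 marks background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.feature import match_template
from skimage.segmentation import watershed

from .core import ImageStack
from .fluorescence import project_apical
from .geometry import polygon_area

__all__ = [
    "SeedSet",
    "LabelImage",
    "PivField",
    "CellTrack",
    "seeded_watershed",
    "piv_displacement",
    "propagate_seeds",
    "track_tissue",
]

#: normalized cross-correlation below which a PIV match is not trusted
CONFIDENT_NCC = 0.5


@dataclass
class SeedSet:
    """Per-frame marker points: (cell_id, x, y) in pixels; id 0 = background."""

    frame: int
    seeds: list[tuple[int, float, float]]

    def validate(self, shape: tuple[int, int]) -> None:
        ids = [cid for cid, _, _ in self.seeds]
        nonzero = [c for c in ids if c != 0]
        if len(nonzero) != len(set(nonzero)):
            raise ValueError("one seed per tracked cell: duplicate cell ids")
        for cid, x, y in self.seeds:
            if not (0 <= x < shape[1] and 0 <= y < shape[0]):
                raise ValueError(f"seed for cell {cid} at ({x:g}, {y:g}) lies outside the image")


@dataclass
class LabelImage:
    """Watershed result: per-pixel cell ids plus diagnostic warnings."""

    labels: np.ndarray
    warnings: list[str] = field(default_factory=list)


@dataclass
class PivField:
    """Displacement field on a regular grid (pixels)."""

    xs: np.ndarray  # grid-point x coordinates
    ys: np.ndarray  # grid-point y coordinates
    dx: np.ndarray  # (len(ys), len(xs))
    dy: np.ndarray
    confidence: np.ndarray  # peak NCC per grid point

    def at(self, x: float, y: float) -> tuple[float, float, float]:
        """Displacement and confidence at the nearest grid point."""
        i = int(np.argmin(np.abs(self.ys - y)))
        j = int(np.argmin(np.abs(self.xs - x)))
        return float(self.dx[i, j]), float(self.dy[i, j]), float(self.confidence[i, j])


@dataclass
class CellTrack:
    """Per-frame polygon (µm) and area (µm²) of one tracked cell.

    Frames where the cell was lost hold ``None`` / NaN.
    """

    cell_id: int
    polygons: list[np.ndarray | None]
    areas: np.ndarray


def _markers_from_seeds(seeds: SeedSet, shape: tuple[int, int]) -> tuple[np.ndarray, int]:
    markers = np.zeros(shape, dtype=np.int32)
    bg_marker = max((cid for cid, _, _ in seeds.seeds), default=0) + 1
    for cid, x, y in seeds.seeds:
        markers[int(round(y)), int(round(x))] = cid if cid != 0 else bg_marker
    return markers, bg_marker


def _shared_basin_warnings(frame: np.ndarray, seeds: SeedSet) -> list[str]:
    """Flag seed pairs with no intensity ridge between them.

    The straight path between two seeds is sampled; if it never rises
    above both endpoint intensities (beyond 1% of the image range), the
    seeds sit in one basin and the caller should merge or reseed.
    """
    warnings = []
    span = float(np.ptp(frame))
    pts = [(cid, x, y) for cid, x, y in seeds.seeds if cid != 0]
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            c1, x1, y1 = pts[i]
            c2, x2, y2 = pts[j]
            n = max(int(np.hypot(x2 - x1, y2 - y1)), 2)
            xs = np.linspace(x1, x2, n)
            ys = np.linspace(y1, y2, n)
            prof = ndimage.map_coordinates(frame.astype(float), [ys, xs], order=1)
            if prof.max() <= max(prof[0], prof[-1]) + 0.01 * span:
                warnings.append(f"seeds {c1} and {c2} appear to share one basin")
    return warnings


def seeded_watershed(
    frame: np.ndarray, seeds: SeedSet, presmooth_sigma: float = 1.0
) -> LabelImage:
    """Expand seeds to cell regions with marker-based watershed.

    The membrane intensity itself is the elevation map (ridges high), so
    basins grow until they meet at membranes; flooding order is
    deterministic.  Ridge pixels are assigned to the basin that reaches
    them first.  Seed pairs that appear to share one basin are reported in
    ``warnings`` — both regions are still returned.
    """
    if not seeds.seeds:
        raise ValueError("need at least one seed")
    frame = np.asarray(frame, dtype=float)
    seeds.validate(frame.shape)
    elevation = ndimage.gaussian_filter(frame, presmooth_sigma) if presmooth_sigma > 0 else frame
    markers, bg_marker = _markers_from_seeds(seeds, frame.shape)
    labels = watershed(elevation, markers=markers).astype(np.int32)
    labels[labels == bg_marker] = 0
    return LabelImage(labels=labels, warnings=_shared_basin_warnings(frame, seeds))


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2 * c0 + cp1
    if denom == 0:
        return 0.0
    off = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(off, -1.0, 1.0))


def piv_displacement(
    frame_t: np.ndarray,
    frame_t1: np.ndarray,
    window: int = 32,
    spacing: int = 16,
    subpixel: bool = True,
) -> PivField:
    """Particle-image-velocimetry displacement field between two frames.

    For each grid point, the ``window``-sized patch of ``frame_t`` is
    matched against a search region of ``frame_t1`` (maximum displacement
    half a window) by normalized cross-correlation; the correlation peak,
    refined by a parabolic fit, gives (dx, dy), and the peak NCC value is
    the confidence.  A flat (zero-variance) window yields displacement 0
    with confidence 0.
    """
    if window < 8:
        raise ValueError("window must be at least 8 px")
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t1 = np.asarray(frame_t1, dtype=float)
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frames must have the same shape")
    h, w = frame_t.shape
    half = window // 2
    margin = window // 2  # max displacement searched

    xs = np.arange(half, w - half + 1, spacing)
    ys = np.arange(half, h - half + 1, spacing)
    dx = np.zeros((ys.size, xs.size))
    dy = np.zeros((ys.size, xs.size))
    conf = np.zeros((ys.size, xs.size))

    for i, yc in enumerate(ys):
        for j, xc in enumerate(xs):
            tpl = frame_t[yc - half : yc + half, xc - half : xc + half]
            if np.ptp(tpl) == 0:
                continue  # flat window: displacement 0, confidence 0
            y0 = max(yc - half - margin, 0)
            y1 = min(yc + half + margin, h)
            x0 = max(xc - half - margin, 0)
            x1 = min(xc + half + margin, w)
            search = frame_t1[y0:y1, x0:x1]
            if np.ptp(search) == 0:
                continue
            corr = match_template(search, tpl)
            pk = np.unravel_index(int(np.argmax(corr)), corr.shape)
            best = float(corr[pk])
            ddy = pk[0] + y0 - (yc - half)
            ddx = pk[1] + x0 - (xc - half)
            if subpixel:
                if 0 < pk[0] < corr.shape[0] - 1:
                    ddy += _parabolic_offset(
                        corr[pk[0] - 1, pk[1]], corr[pk[0], pk[1]], corr[pk[0] + 1, pk[1]]
                    )
                if 0 < pk[1] < corr.shape[1] - 1:
                    ddx += _parabolic_offset(
                        corr[pk[0], pk[1] - 1], corr[pk[0], pk[1]], corr[pk[0], pk[1] + 1]
                    )
            dx[i, j] = ddx
            dy[i, j] = ddy
            conf[i, j] = best

    return PivField(xs=xs, ys=ys, dx=dx, dy=dy, confidence=conf)


def propagate_seeds(
    labels: LabelImage | np.ndarray, seeds: SeedSet, piv_field: PivField
) -> tuple[SeedSet, list[int]]:
    """Advect seeds by the local PIV displacement to the next frame.

    A seed whose advected position no longer falls inside its own region
    is snapped to the region centroid plus the local displacement; a seed
    leaving the image marks its cell as lost.  Returns the new
    :class:`SeedSet` and the list of lost cell ids.
    """
    lab = labels.labels if isinstance(labels, LabelImage) else labels
    shape = lab.shape
    new_seeds: list[tuple[int, float, float]] = []
    lost: list[int] = []
    for cid, x, y in seeds.seeds:
        ddx, ddy, _ = piv_field.at(x, y)
        nx, ny = x + ddx, y + ddy
        if cid != 0:
            ix, iy = int(round(np.clip(nx, 0, shape[1] - 1))), int(round(np.clip(ny, 0, shape[0] - 1)))
            inside_image = 0 <= nx < shape[1] and 0 <= ny < shape[0]
            if not inside_image or lab[iy, ix] != cid:
                mask = lab == cid
                if not np.any(mask):
                    lost.append(cid)
                    continue
                cy, cx = ndimage.center_of_mass(mask)
                cdx, cdy, _ = piv_field.at(cx, cy)
                nx, ny = cx + cdx, cy + cdy
        if not (0 <= nx < shape[1] and 0 <= ny < shape[0]):
            if cid != 0:
                lost.append(cid)
            continue
        new_seeds.append((cid, float(nx), float(ny)))
    return SeedSet(frame=seeds.frame + 1, seeds=new_seeds), lost


def _label_polygon(mask: np.ndarray, pixel_size: float) -> np.ndarray | None:
    contours = skmeasure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # outer boundary
    # (row, col) → (x, y) µm
    return np.column_stack([contour[:, 1], contour[:, 0]]) * pixel_size


def track_tissue(
    stack: ImageStack,
    initial_seeds: SeedSet,
    channel: int | str = 0,
    n_apical_slices: int = 3,
    presmooth_sigma: float = 1.0,
    piv_window: int = 32,
    piv_spacing: int = 16,
) -> tuple[list[CellTrack], np.ndarray]:
    """Segment and track all seeded cells through a movie.

    Alternates seeded watershed and PIV seed propagation over frames;
    segmentation runs on a maximum-intensity projection of the
    ``n_apical_slices`` most apical z-planes.  Emits one
    :class:`CellTrack` per initial cell seed (marching-squares boundary
    polygon in µm and shoelace area per frame) and the full label stack.
    Raises if every cell is lost before the movie ends.
    """
    n_slices = min(n_apical_slices, stack.n_slices)
    frames = project_apical(stack, n_slices=n_slices, channel=channel)
    n = stack.n_frames
    cell_ids = sorted(cid for cid, _, _ in initial_seeds.seeds if cid != 0)
    if not cell_ids:
        raise ValueError("initial seeds contain no cells")

    tracks = {
        cid: CellTrack(cell_id=cid, polygons=[None] * n, areas=np.full(n, np.nan))
        for cid in cell_ids
    }
    label_stack = np.zeros((n, *stack.shape_yx), dtype=np.int32)

    seeds = initial_seeds
    for f in range(n):
        if not any(cid != 0 for cid, _, _ in seeds.seeds):
            raise RuntimeError(f"all cells lost by frame {f}")
        result = seeded_watershed(frames[f], seeds, presmooth_sigma=presmooth_sigma)
        label_stack[f] = result.labels
        for cid, _, _ in seeds.seeds:
            if cid == 0:
                continue
            mask = result.labels == cid
            poly = _label_polygon(mask, stack.pixel_size)
            if poly is not None and poly.shape[0] >= 3:
                tracks[cid].polygons[f] = poly
                tracks[cid].areas[f] = polygon_area(poly)
        if f + 1 < n:
            field = piv_displacement(
                frames[f], frames[f + 1], window=piv_window, spacing=piv_spacing
            )
            seeds, _ = propagate_seeds(result, seeds, field)

    return [tracks[cid] for cid in cell_ids], label_stack
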