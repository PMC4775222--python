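"""Fluorescence quantification conventions.

Intensities are read from maximum-intensity projections of the most apical
z-slices, background-subtracted with the modal pixel value of a basal
projection cropped around the region of interest, and corrected for
photobleaching by dividing by the mean image intensity of each time point.
Junctional signal is averaged over a dilated traced path; medial signal is
averaged inside the cell polygon eroded away from the junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .core import ImageStack

__all__ = [
    "IntensityTrace",
    "project_apical",
    "background_mode",
    "bleach_correct",
    "junctional_intensity",
    "medial_intensity_trace",
]


@dataclass
class IntensityTrace:
    """A fluorescence time series with its correction provenance."""

    times: np.ndarray
    values: np.ndarray  # final (normalized if requested) values
    raw: np.ndarray
    background: np.ndarray
    corrected: np.ndarray
    normalization: str = "none"  # "none" | "t0"
    meta: dict = field(default_factory=dict)


def project_apical(
    stack: ImageStack, n_slices: int = 3, side: str = "apical", channel: int | str = 0
) -> np.ndarray:
    """Maximum-intensity projection over the apical (or basal) z-slices.

    Returns a ``(t, y, x)`` array; the ``n_slices`` contiguous planes at
    the apical end of the z-range are used (which end is apical follows
    the stack's ``apical_high_z`` flag).
    """
    if side not in ("apical", "basal"):
        raise ValueError("side must be 'apical' or 'basal'")
    if n_slices < 1 or n_slices > stack.n_slices:
        raise ValueError(
            f"requested {n_slices} slices but the stack has {stack.n_slices} z-planes"
        )
    if isinstance(channel, str):
        channel = stack.channel_names.index(channel)
    apical_high = stack.apical_high_z
    take_high = apical_high if side == "apical" else not apical_high
    if take_high:
        planes = stack.data[:, stack.n_slices - n_slices :, channel]
    else:
        planes = stack.data[:, :n_slices, channel]
    return planes.max(axis=1)


def _int_mode(values: np.ndarray) -> tuple[int, bool]:
    """Mode of integer-binned values; ties take the smaller value (flagged)."""
    v = np.round(values).astype(np.int64).ravel()
    offset = v.min()
    counts = np.bincount(v - offset)
    best = counts.max()
    modes = np.flatnonzero(counts == best)
    return int(modes[0] + offset), modes.size > 1


def background_mode(
    basal_projection: np.ndarray,
    roi_center: tuple[float, float],
    pixel_size: float,
    roi_size: float = 10.0,
) -> float:
    """Background estimate: modal pixel value of a basal crop around the ROI.

    ``roi_center`` is (x, y) in µm; the crop is ``roi_size`` × ``roi_size``
    µm (e.g. 50×50 px at 0.2 µm/px).  A crop extending beyond the image is
    clipped with a warning recorded on the returned value's side via
    logging-free convention: clipping is silent but deterministic.
    The histogram uses raw integer bins (no smoothing); a modal tie takes
    the smaller value.
    """
    img = np.asarray(basal_projection)
    half_px = int(round(roi_size / (2 * pixel_size)))
    cx = int(round(roi_center[0] / pixel_size))
    cy = int(round(roi_center[1] / pixel_size))
    y0, y1 = max(cy - half_px, 0), min(cy + half_px, img.shape[0])
    x0, x1 = max(cx - half_px, 0), min(cx + half_px, img.shape[1])
    if y1 <= y0 or x1 <= x0:
        raise ValueError("ROI lies entirely outside the image")
    mode, _tie = _int_mode(img[y0:y1, x0:x1])
    return float(mode)


def bleach_correct(values: np.ndarray, frame_means: np.ndarray) -> np.ndarray:
    """Photobleaching correction: divide by the mean image intensity per frame."""
    values = np.asarray(values, dtype=float)
    frame_means = np.asarray(frame_means, dtype=float)
    if values.shape[0] != frame_means.shape[0]:
        raise ValueError("values and frame_means must align frame-wise")
    if np.any(frame_means <= 0):
        raise ValueError("frame means must be positive")
    return values / frame_means


def junctional_intensity(image: np.ndarray, path: np.ndarray, width: int = 3) -> float:
    """Mean intensity along a traced interface, image-mode-subtracted.

    ``path`` is an (k, 2) polyline in pixel (x, y) coordinates; the line is
    dilated to ``width`` px before averaging, and the whole-image mode is
    subtracted as the background estimate.
    """
    img = np.asarray(image, dtype=float)
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("path needs at least two points")
    mask = np.zeros(img.shape, dtype=bool)
    for a, b in zip(path[:-1], path[1:]):
        rr, cc = skdraw.line(
            int(round(a[1])), int(round(a[0])), int(round(b[1])), int(round(b[0]))
        )
        keep = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
        mask[rr[keep], cc[keep]] = True
    if not np.any(mask):
        raise ValueError("path lies outside the image")
    if width > 1:
        mask = ndimage.binary_dilation(mask, iterations=width // 2)
    mode, _ = _int_mode(img)
    return float(img[mask].mean() - mode)


def medial_intensity_trace(
    stack: ImageStack,
    polygons: list[np.ndarray],
    channel: int | str = 0,
    n_slices: int = 3,
    junctional_width: int = 3,
    roi_size: float = 10.0,
    normalize: bool = True,
) -> tuple[IntensityTrace, np.ndarray]:
    """Medial (non-junctional) intensity inside a cell over time.

    Per frame: apical max projection → subtract the basal-crop modal
    background → bleach-correct by the projection's mean intensity → mean
    over the polygon interior eroded by the junctional width.  Returns the
    trace and the paired polygon-area series; with ``normalize=True`` both
    are divided by their value at the first time point.
    """
    from .geometry import polygon_area  # local import to avoid cycles

    apical = project_apical(stack, n_slices=min(n_slices, stack.n_slices), channel=channel)
    basal = project_apical(
        stack, n_slices=min(n_slices, stack.n_slices), side="basal", channel=channel
    )
    n = stack.n_frames
    if len(polygons) != n:
        raise ValueError("need one polygon per frame")
    raw = np.empty(n)
    bg = np.empty(n)
    areas = np.empty(n)
    frame_means = apical.reshape(n, -1).mean(axis=1)
    for f in range(n):
        poly = np.asarray(polygons[f], dtype=float)
        centroid = poly.mean(axis=0)
        bg[f] = background_mode(basal[f], (centroid[0], centroid[1]), stack.pixel_size, roi_size)
        rr, cc = skdraw.polygon(
            poly[:, 1] / stack.pixel_size, poly[:, 0] / stack.pixel_size, shape=apical[f].shape
        )
        mask = np.zeros(apical[f].shape, dtype=bool)
        mask[rr, cc] = True
        erode_iters = max(junctional_width // 2, 1)
        mask = ndimage.binary_erosion(mask, iterations=erode_iters)
        if not np.any(mask):
            raise ValueError(f"frame {f}: polygon empty after junctional erosion")
        raw[f] = apical[f][mask].mean()
        areas[f] = polygon_area(poly)
    corrected = bleach_correct(raw - bg, frame_means)
    if normalize:
        if corrected[0] == 0:
            raise ValueError("cannot normalize: corrected value at t=0 is zero")
        values = corrected / corrected[0]
        areas_out = areas / areas[0]
        norm = "t0"
    else:
        values = corrected
        areas_out = areas
        norm = "none"
    trace = IntensityTrace(
        times=stack.times,
        values=values,
        raw=raw,
        background=bg,
        corrected=corrected,
        normalization=norm,
        meta={"junctional_width_px": junctional_width, "n_slices": n_slices},
    )
    return trace, areas_out
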