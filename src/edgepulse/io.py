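"""CSV / TIFF / JSON persistence for every pipeline stage.

Tabular outputs are plain CSV with a header; image stacks are multi-page
TIFF with the axis order recorded in the image description; each writer
can drop a JSON run-metadata sidecar (package version, config hash, seed)
next to its output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .ablation import AblationEvent
from .core import EdgeTrace, ImageStack, TissueTimeSeries
from .resolution import ResolutionEvent
from .segmentation import CellTrack

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_labels_tiff",
    "read_labels_tiff",
    "write_tissue_csv",
    "read_tissue_csv",
    "write_tracks_csv",
    "write_edge_csv",
    "read_edge_csv",
    "write_events_csv",
    "write_ablation_csv",
    "read_ablation_csv",
    "write_signal_csv",
    "read_signal_csv",
    "write_metadata",
]

AXES = "TZCYX"


def write_metadata(path: str | Path, config: dict, seed: int | None = None) -> None:
    """JSON sidecar: package version, config hash, seed, full config."""
    blob = json.dumps(config, sort_keys=True, default=str)
    meta = {
        "version": __version__,
        "config_sha1": hashlib.sha1(blob.encode()).hexdigest(),
        "seed": seed,
        "config": json.loads(blob),
    }
    Path(path).write_text(json.dumps(meta, indent=2))


def write_stack_tiff(path: str | Path, stack: ImageStack) -> None:
    meta = {
        "axes": AXES,
        "pixel_size_um": stack.pixel_size,
        "dt_s": stack.dt,
        "channel_names": stack.channel_names,
        "apical_high_z": stack.apical_high_z,
    }
    tifffile.imwrite(path, stack.data.astype(np.float32), description=json.dumps(meta))


def read_stack_tiff(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    data = data.reshape(data.shape[-5:]) if data.ndim >= 5 else data.reshape(
        (1,) * (5 - data.ndim) + data.shape
    )
    return ImageStack(
        data=data,
        pixel_size=meta["pixel_size_um"],
        dt=meta["dt_s"],
        channel_names=meta["channel_names"],
        apical_high_z=meta.get("apical_high_z", True),
    )


def write_labels_tiff(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def _polygon_to_json(poly: np.ndarray | None) -> str:
    if poly is None:
        return "[]"
    return json.dumps(np.asarray(poly).round(6).tolist())


def write_tissue_csv(path: str | Path, tissue: TissueTimeSeries) -> None:
    """One row per cell per frame: frame, time_s, cell_id, polygon_json, area_um2."""
    rows = []
    for cid in tissue.cell_ids:
        for f, t in enumerate(tissue.times):
            rows.append(
                {
                    "frame": f,
                    "time_s": t,
                    "cell_id": cid,
                    "polygon_json": _polygon_to_json(tissue.polygons[cid][f]),
                    "area_um2": tissue.areas[cid][f],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tissue_csv(path: str | Path) -> TissueTimeSeries:
    df = pd.read_csv(path)
    times = np.sort(df["time_s"].unique())
    polygons: dict[int, list[np.ndarray]] = {}
    areas: dict[int, np.ndarray] = {}
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("frame")
        polygons[int(cid)] = [np.asarray(json.loads(s), dtype=float) for s in grp["polygon_json"]]
        areas[int(cid)] = grp["area_um2"].to_numpy()
    return TissueTimeSeries(times=times, polygons=polygons, areas=areas)


def write_tracks_csv(path: str | Path, tracks: list[CellTrack], times: np.ndarray) -> None:
    rows = []
    for tr in tracks:
        for f, t in enumerate(times):
            rows.append(
                {
                    "frame": f,
                    "time_s": t,
                    "cell_id": tr.cell_id,
                    "area_um2": tr.areas[f],
                    "polygon_json": _polygon_to_json(tr.polygons[f]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_edge_csv(path: str | Path, trace: EdgeTrace, orientation_deg: float | None = None) -> None:
    if trace.endpoints is None:
        raise ValueError("edge trace carries no endpoint coordinates")
    rows = []
    for f, t in enumerate(trace.times):
        (x1, y1), (x2, y2) = trace.endpoints[f]
        rows.append(
            {
                "frame": f,
                "time_s": t,
                "edge_id": trace.edge_id,
                "x1": x1,
                "y1": y1,
                "x2": x2,
                "y2": y2,
                "length_um": trace.lengths[f],
                "orientation_deg": orientation_deg if orientation_deg is not None else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_edge_csv(path: str | Path, edge_id: str | None = None) -> EdgeTrace:
    df = pd.read_csv(path)
    if edge_id is not None:
        df = df[df["edge_id"] == edge_id]
    if df.empty:
        raise ValueError(f"no rows for edge {edge_id!r}")
    df = df.sort_values("frame")
    endpoints = np.stack(
        [df[["x1", "y1"]].to_numpy(), df[["x2", "y2"]].to_numpy()], axis=1
    )
    return EdgeTrace(
        edge_id=str(df["edge_id"].iloc[0]),
        times=df["time_s"].to_numpy(),
        lengths=df["length_um"].to_numpy(),
        endpoints=endpoints,
    )


def write_events_csv(path: str | Path, events: list[ResolutionEvent]) -> None:
    rows = [
        {
            "edge_id": e.edge_id,
            "t0_s": e.t0,
            "status": e.status.value,
            "angle_deg": e.orientation_deg,
            "sector": e.sector,
            "rate_um_per_min": e.elongation_rate,
            "window_s": e.rate_window,
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ablation_csv(path: str | Path, events: list[AblationEvent]) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "edge_id": e.edge_id,
                "class": e.edge_class,
                "x1_pre": e.pre1[0],
                "y1_pre": e.pre1[1],
                "x2_pre": e.pre2[0],
                "y2_pre": e.pre2[1],
                "x1_post": e.post1[0] if e.post1 is not None else np.nan,
                "y1_post": e.post1[1] if e.post1 is not None else np.nan,
                "x2_post": e.post2[0] if e.post2 is not None else np.nan,
                "y2_post": e.post2[1] if e.post2 is not None else np.nan,
                "t_ablation_s": e.t_ablation,
                "t_acquisition_s": e.t_acquisition,
                "theta1_deg": e.theta1,
                "theta2_deg": e.theta2,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ablation_csv(path: str | Path) -> list[AblationEvent]:
    df = pd.read_csv(path)
    events = []
    for _, r in df.iterrows():
        post1 = None if np.isnan(r["x1_post"]) else np.array([r["x1_post"], r["y1_post"]])
        post2 = None if np.isnan(r["x2_post"]) else np.array([r["x2_post"], r["y2_post"]])
        events.append(
            AblationEvent(
                edge_id=str(r["edge_id"]),
                pre1=np.array([r["x1_pre"], r["y1_pre"]]),
                pre2=np.array([r["x2_pre"], r["y2_pre"]]),
                post1=post1,
                post2=post2,
                t_ablation=float(r["t_ablation_s"]),
                t_acquisition=float(r["t_acquisition_s"]),
                edge_class=str(r["class"]),
                theta1=None if pd.isna(r["theta1_deg"]) else float(r["theta1_deg"]),
                theta2=None if pd.isna(r["theta2_deg"]) else float(r["theta2_deg"]),
            )
        )
    return events


def write_signal_csv(path: str | Path, times: np.ndarray, values: np.ndarray, label: str = "") -> None:
    pd.DataFrame({"time_s": times, "value": values, "label": label}).to_csv(path, index=False)


def read_signal_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, str]:
    df = pd.read_csv(path)
    label = str(df["label"].iloc[0]) if "label" in df and len(df) else ""
    return df["time_s"].to_numpy(), df["value"].to_numpy(), label
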