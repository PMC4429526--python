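"""Readers and writers for the pipeline's on-disk formats.

Movies travel as multi-page TIFF; 1-D traces as two-column CSV
(``time_s,value``) with a JSON sidecar carrying the sampling metadata; ROI
masks as labeled TIFF plus a CSV of centroids and areas; activity maps as
PNG + CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .imaging import ROI, FrameStack


def save_stack(path: str | Path, stack: FrameStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"frame_rate": stack.frame_rate, **stack.origin}))


def load_stack(path: str | Path, frame_rate: float | None = None) -> FrameStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fr = frame_rate if frame_rate is not None else meta.pop("frame_rate", None)
    if fr is None:
        raise ValueError("frame_rate not given and no sidecar metadata found")
    return FrameStack(data=np.asarray(data, dtype=float), frame_rate=float(fr), origin=meta)


def save_trace(path: str | Path, values: np.ndarray, sample_rate: float, **meta) -> None:
    path = Path(path)
    t = np.arange(len(values)) / sample_rate
    pd.DataFrame({"time_s": t, "value": values}).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"sample_rate": sample_rate, **meta}))


def load_trace(path: str | Path) -> tuple[np.ndarray, float, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if "sample_rate" in meta:
        fs = float(meta.pop("sample_rate"))
    else:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    return df["value"].to_numpy(dtype=float), fs, meta


def save_rois(path_prefix: str | Path, rois: Sequence[ROI], shape: tuple[int, int]) -> None:
    """Write ROI masks as a labeled TIFF and a CSV of centroids/areas."""
    prefix = Path(path_prefix)
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    for roi in rois:
        rr, cc = zip(*roi.pixels)
        labels[list(rr), list(cc)] = roi.label
        rows.append(
            {
                "label": roi.label,
                "centroid_row": roi.centroid[0],
                "centroid_col": roi.centroid[1],
                "area_px": roi.area,
            }
        )
    tifffile.imwrite(prefix.with_suffix(".tif"), labels)
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".csv"), index=False)


def save_map_png(path: str | Path, image: np.ndarray, cmap: str = "magma") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(image, cmap=cmap)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_stim_log(path: str | Path, onsets_s: Sequence[float], duration_ms: float) -> None:
    pd.DataFrame({"onset_s": onsets_s, "duration_ms": duration_ms}).to_csv(path, index=False)


def load_stim_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
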