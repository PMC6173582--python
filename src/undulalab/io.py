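"""Readers and writers for the pipeline's on-disk formats.

Stacks are multi-frame grayscale TIFF (via tifffile); tabular outputs are
plain CSV so they round-trip through any downstream stats environment.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import Midline
from .synthetic import GroundTruth, LocomotionParams, PerturbationEpoch

__all__ = [
    "save_stack", "load_stack",
    "midlines_to_frame", "midlines_from_frame", "midline_qc_frame",
    "truth_track_frame", "truth_midline_frame",
    "save_params", "load_params",
    "correlogram_frame", "save_kymograph_png",
]


def save_stack(path: str | Path, frames: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(frames))


def load_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def midlines_to_frame(midlines: list[Midline]) -> pd.DataFrame:
    """Long-format (frame, point_idx, row, col); invalid frames omitted."""
    rows = []
    for i, m in enumerate(midlines):
        if m.valid:
            for j, (r, c) in enumerate(m.points):
                rows.append((i, j, r, c))
    return pd.DataFrame(rows, columns=["frame", "point_idx", "row", "col"])


def midlines_from_frame(df: pd.DataFrame, n_frames: int | None = None) -> list[Midline]:
    n_frames = int(df["frame"].max()) + 1 if n_frames is None else n_frames
    out = []
    groups = {int(k): g for k, g in df.groupby("frame")}
    for i in range(n_frames):
        if i not in groups:
            out.append(Midline.invalid_frame("no_worm"))
            continue
        g = groups[i].sort_values("point_idx")
        pts = g[["row", "col"]].to_numpy(dtype=float)
        d = np.diff(pts, axis=0)
        out.append(Midline(points=pts,
                           theta=np.arctan2(d[:, 0], d[:, 1]),
                           arc_length_px=float(np.linalg.norm(d, axis=1).sum())))
    return out


def midline_qc_frame(midlines: list[Midline]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i, m.valid, m.invalid_reason or "", m.arc_length_px)
         for i, m in enumerate(midlines)],
        columns=["frame", "valid", "invalid_reason", "arc_length_px"])


def truth_track_frame(truth: GroundTruth) -> pd.DataFrame:
    """One row per frame: time, centroid, length, locomotion state."""
    return pd.DataFrame({
        "frame": np.arange(truth.n_frames),
        "time_s": truth.time_s,
        "x_mm": truth.centroid_mm[:, 0],
        "y_mm": truth.centroid_mm[:, 1],
        "length_mm": truth.arc_length_mm,
        "state": truth.state,
    })


def truth_midline_frame(truth: GroundTruth) -> pd.DataFrame:
    T, n, _ = truth.midline_mm.shape
    frames = np.repeat(np.arange(T), n)
    idx = np.tile(np.arange(n), T)
    flat = truth.midline_mm.reshape(-1, 2)
    return pd.DataFrame({"frame": frames, "point_idx": idx,
                         "x_mm": flat[:, 0], "y_mm": flat[:, 1]})


def save_params(path: str | Path, params: LocomotionParams) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(params), indent=2))


def load_params(path: str | Path) -> LocomotionParams:
    d = json.loads(Path(path).read_text())
    d["perturbation_epochs"] = tuple(
        PerturbationEpoch(**e) for e in d.get("perturbation_epochs", []))
    return LocomotionParams(**d)


def correlogram_frame(cset) -> pd.DataFrame:
    return pd.DataFrame({"lag_s": cset.lags_s, "mean": cset.mean,
                         "sem": cset.sem,
                         "n_events": (~np.isnan(cset.per_event)).sum(axis=0)})


def save_kymograph_png(path: str | Path, kymograph: np.ndarray,
                       fps: float) -> None:
    """Render a time x body-position bending kymograph (blue/red diverging)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lim = np.nanmax(np.abs(kymograph)) or 1.0
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(kymograph.T, aspect="auto", cmap="RdBu_r",
                   vmin=-lim, vmax=lim,
                   extent=(0, kymograph.shape[0] / fps, 100, 0))
    ax.set_xlabel("time (s)")
    ax.set_ylabel("body point (head → tail)")
    fig.colorbar(im, ax=ax, label="normalized 2-point angle (rad)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
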