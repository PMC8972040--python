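"""CSV/TIFF/JSON interchange for traces, scans and waveforms.

CSV is the interchange backbone (bit-exact and diff-able); TIFF appears
only at the image boundary.  Ground truth travels as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError
from .frap import FrapTrace
from .waveform import LineScan, SarcomereWaveform

_ROI_COLUMNS = {
    ("converted", "green"): "green_converted",
    ("reference", "green"): "green_reference",
    ("converted", "red"): "red_converted",
    ("nonconverted", "red"): "red_nonconverted",
}


def frap_trace_to_frame(trace: FrapTrace) -> pd.DataFrame:
    """Long-format (time_min, roi, channel, mean_intensity) rows for one trace."""
    rows = []
    for (roi, channel), attr in _ROI_COLUMNS.items():
        for t, v in zip(trace.times_h, getattr(trace, attr)):
            rows.append(
                {
                    "time_min": t * 60.0,
                    "roi": roi,
                    "channel": channel,
                    "mean_intensity": v,
                    "trace_id": trace.source_id,
                }
            )
    return pd.DataFrame(rows)


def read_frap_csv(path: str | Path, pre_index: int = 0, post_index: int = 1) -> list[FrapTrace]:
    """Read FRAP traces from a long-format CSV (one trace per trace_id)."""
    df = pd.read_csv(path)
    required = {"time_min", "roi", "channel", "mean_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidConfigurationError(f"FRAP CSV missing columns: {sorted(missing)}")
    if "trace_id" not in df.columns:
        df["trace_id"] = ""
    traces = []
    for tid, sub in df.groupby("trace_id", sort=True):
        series = {}
        for (roi, channel), attr in _ROI_COLUMNS.items():
            sel = sub[(sub["roi"] == roi) & (sub["channel"] == channel)]
            sel = sel.sort_values("time_min")
            if sel.empty:
                raise InvalidConfigurationError(
                    f"trace {tid!r}: missing roi={roi!r} channel={channel!r}"
                )
            series[attr] = sel["mean_intensity"].to_numpy(float)
            series.setdefault("times_h", sel["time_min"].to_numpy(float) / 60.0)
        traces.append(
            FrapTrace(
                pre_index=pre_index,
                post_index=post_index,
                source_id=str(tid),
                **series,
            )
        )
    return traces


def write_frap_csv(traces: Sequence[FrapTrace], path: str | Path) -> None:
    pd.concat([frap_trace_to_frame(t) for t in traces], ignore_index=True).to_csv(
        path, index=False
    )


def scans_to_frame(scans: Sequence[LineScan]) -> pd.DataFrame:
    """Long-format line scans (source_id, myotube, time_min, position, channels)."""
    frames = []
    for s in scans:
        frames.append(
            pd.DataFrame(
                {
                    "source_id": s.source_id,
                    "myotube": s.myotube if s.myotube is not None else -1,
                    "time_min": s.time_min,
                    "position_um": s.positions_um,
                    "green": s.green,
                    "red": s.red,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def read_scans_csv(path: str | Path) -> list[LineScan]:
    df = pd.read_csv(path)
    scans = []
    for (sid, t), sub in df.groupby(["source_id", "time_min"], sort=True):
        sub = sub.sort_values("position_um")
        myotube = int(sub["myotube"].iloc[0]) if "myotube" in sub.columns else None
        scans.append(
            LineScan(
                positions_um=sub["position_um"].to_numpy(float),
                green=sub["green"].to_numpy(float),
                red=sub["red"].to_numpy(float),
                time_min=float(t),
                source_id=str(sid),
                myotube=None if myotube in (None, -1) else myotube,
            )
        )
    return scans


def waveforms_to_frame(waveforms: Sequence[SarcomereWaveform]) -> pd.DataFrame:
    """Long-format normalized waveforms with per-sarcomere metadata columns."""
    frames = []
    for w in waveforms:
        frames.append(
            pd.DataFrame(
                {
                    "source_id": w.source_id,
                    "myotube": w.myotube if w.myotube is not None else -1,
                    "time_min": w.time_min,
                    "x_norm": w.x,
                    "green_norm": w.green,
                    "red_norm": w.red,
                    "green_range": w.green_range,
                    "red_range": w.red_range,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def read_waveforms_csv(path: str | Path) -> list[SarcomereWaveform]:
    df = pd.read_csv(path)
    out = []
    for (sid, t), sub in df.groupby(["source_id", "time_min"], sort=True):
        sub = sub.sort_values("x_norm")
        myotube = int(sub["myotube"].iloc[0]) if "myotube" in sub.columns else -1
        x = sub["x_norm"].to_numpy(float)
        out.append(
            SarcomereWaveform(
                x=x,
                green=sub["green_norm"].to_numpy(float),
                red=sub["red_norm"].to_numpy(float),
                green_range=float(sub["green_range"].iloc[0]),
                red_range=float(sub["red_range"].iloc[0]),
                turning_points_um=(np.nan, np.nan),
                baseline_green=(np.nan, np.nan),
                baseline_red=(np.nan, np.nan),
                degree=-1,
                green_empty=float(sub["green_range"].iloc[0]) <= 0,
                red_empty=float(sub["red_range"].iloc[0]) <= 0,
                time_min=float(t),
                source_id=str(sid),
                myotube=None if myotube == -1 else myotube,
            )
        )
    return out


def write_scan_tiff(scans: Sequence[LineScan], path: str | Path, height_px: int = 11) -> None:
    """Write scans as a multi-page TIFF, one page per scan per channel."""
    import tifffile

    pages = []
    for s in scans:
        pages.append(np.tile(s.green, (height_px, 1)).astype(np.float32))
        pages.append(np.tile(s.red, (height_px, 1)).astype(np.float32))
    tifffile.imwrite(path, np.stack(pages))


def read_scan_tiff(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF into an array of (n_pages, height, width)."""
    import tifffile

    return np.asarray(tifffile.imread(path))


def write_truth_json(path: str | Path, **payload) -> None:
    """Ground-truth sidecar (seed, preset, categories, replaced-fraction...)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "value"):
            return o.value
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default, sort_keys=True))
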