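"""File formats and ROI reduction.

All interchange files are plain delimited text with a single header line and
times in seconds from record start:

* trace files:    ``time_s,P_G,P_R,P_NIR`` at the camera rate
* series files:   ``time_s,spo2`` (truth at 1 Hz; estimates at window centers)
* results tables: one row per (method, scene) with rmse/cc/lag/n columns

Writing uses 12 significant digits so a write/read round trip reproduces
values to well within 1e-9 relative.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .optics import Band, DEFAULT_BANDS
from .series import SpO2Series
from .signals import LuminanceTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_series",
    "write_series",
    "write_results",
    "mean_roi_luminance",
]

_FLOAT_FMT = "%.12g"
_TRACE_COLS = ["time_s", "P_G", "P_R", "P_NIR"]


def _parse_delimited(path, expected_cols: Sequence[str]) -> np.ndarray:
    """Strict CSV reader: raises errors that name the offending line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = [c.strip() for c in header.split(",")]
        if cols != list(expected_cols):
            raise ValueError(
                f"{path}:1: expected header {','.join(expected_cols)!r}, "
                f"got {header!r}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(expected_cols):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(expected_cols)} fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no samples (header-only file)")
    return np.asarray(rows, dtype=float)


def write_trace(path, traces: dict[Band, LuminanceTrace]) -> None:
    """Write a multiband trace set as ``time_s,P_G,P_R,P_NIR``."""
    bands = [Band.G, Band.R, Band.NIR]
    missing = [b.value for b in bands if b not in traces]
    if missing:
        raise KeyError(f"trace set is missing bands {missing}")
    t = traces[Band.G].times
    df = pd.DataFrame(
        {
            "time_s": t,
            **{f"P_{b.value}": traces[b].samples for b in bands},
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trace(path) -> dict[Band, LuminanceTrace]:
    """Read a multiband trace file; the sampling rate is inferred from time."""
    data = _parse_delimited(path, _TRACE_COLS)
    t = data[:, 0]
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples to infer fs")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: time column must be uniformly increasing")
    fs = 1.0 / dt[0]
    out = {}
    for j, band in enumerate((Band.G, Band.R, Band.NIR), start=1):
        out[band] = LuminanceTrace(
            DEFAULT_BANDS[band], data[:, j], fs, t0=float(t[0])
        )
    return out


def write_series(path, series: SpO2Series) -> None:
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series(path, label: str = "") -> SpO2Series:
    data = _parse_delimited(path, ["time_s", "spo2"])
    return SpO2Series(data[:, 0], data[:, 1], label)


def write_results(path, rows: pd.DataFrame | list[dict]) -> None:
    """Write an evaluation results table (method, scene, rmse, cc, ...)."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def mean_roi_luminance(
    frames: dict[Band, np.ndarray] | np.ndarray,
    mask: np.ndarray,
    fs: float,
    t0: float = 0.0,
) -> dict[Band, LuminanceTrace] | LuminanceTrace:
    """Reduce per-band frame stacks to mean-ROI luminance traces.

    Parameters
    ----------
    frames
        Either a ``(T, H, W)`` array for one band or a mapping from band to
        such arrays.
    mask
        Boolean ROI mask of shape ``(H, W)`` with at least one true pixel.
    fs
        Frame rate in Hz.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask selects no pixels")

    def _reduce(stack: np.ndarray, band: Band) -> LuminanceTrace:
        stack = np.asarray(stack, dtype=float)
        if stack.ndim != 3:
            raise ValueError(f"frame stack must be (T, H, W), got {stack.shape}")
        if stack.shape[1:] != mask.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match frames {stack.shape[1:]}"
            )
        samples = stack[:, mask].mean(axis=1)
        return LuminanceTrace(DEFAULT_BANDS[band], samples, fs, t0)

    if isinstance(frames, dict):
        return {Band(b): _reduce(s, Band(b)) for b, s in frames.items()}
    return _reduce(frames, Band.G)
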