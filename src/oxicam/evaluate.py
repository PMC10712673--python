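"""Lag-corrected accuracy protocol and Bland-Altman agreement analysis.

Desaturation reaches different body sites with different circulatory delays,
so a reference oximeter on the fingertip lags (or leads) the face.  The
protocol therefore aligns the reference and estimated series on their
desaturation minima: each series contributes the span of ``half_window_s``
seconds before and after its own global minimum, samples are paired
positionally, and RMSE and Pearson correlation are computed on the pairs.
The recovered lag (estimate minimum time minus reference minimum time) is
reported as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import SpO2Series

__all__ = [
    "EvalConfig",
    "EvalResult",
    "BlandAltman",
    "align_and_score",
    "bland_altman",
    "fraction_within",
]


@dataclass(frozen=True)
class EvalConfig:
    """Protocol parameters: 15 s half-window around the minima, 1 Hz grid."""

    half_window_s: float = 15.0
    resample_hz: float = 1.0
    allow_lag_correction: bool = True

    def __post_init__(self) -> None:
        if self.half_window_s <= 0:
            raise ValueError("half_window_s must be positive")
        if self.resample_hz <= 0:
            raise ValueError("resample_hz must be positive")


@dataclass
class EvalResult:
    rmse: float
    cc: float
    lag_s: float
    n_points: int


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def _resample(series: SpO2Series, hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation to a uniform grid; gaps wider than a step stay nan."""
    finite = np.isfinite(series.values)
    if finite.sum() < 2:
        raise ValueError(
            f"series {series.label!r} has fewer than 2 finite samples"
        )
    t, v = series.times[finite], series.values[finite]
    step = 1.0 / hz
    grid = np.arange(np.ceil(t[0] * hz), np.floor(t[-1] * hz) + 1) * step
    out = np.interp(grid, t, v)
    # a grid point with no finite source sample nearby is itself missing
    nearest = np.searchsorted(t, grid)
    nearest = np.clip(nearest, 1, len(t) - 1)
    dist = np.minimum(np.abs(grid - t[nearest - 1]), np.abs(grid - t[nearest]))
    out[dist > 0.75 * step] = np.nan
    return grid, out


def _min_window(
    grid: np.ndarray, vals: np.ndarray, half_n: int, name: str,
    center_idx: int | None = None,
) -> tuple[int, np.ndarray]:
    idx = int(np.nanargmin(vals)) if center_idx is None else center_idx
    lo, hi = idx - half_n, idx + half_n
    if lo < 0 or hi >= len(vals):
        deficit = max(-lo, hi - (len(vals) - 1))
        raise ValueError(
            f"{name} series: the minimum-centered window extends "
            f"{deficit} sample(s) beyond the record"
        )
    return idx, vals[lo : hi + 1]


def align_and_score(
    ref: SpO2Series, est: SpO2Series, cfg: EvalConfig = EvalConfig()
) -> EvalResult:
    """Score an estimate against a reference on minima-centered windows.

    Both series are resampled to ``cfg.resample_hz``; the global minimum of
    each (earliest if tied) anchors its window of ``2*half_window_s``.  With
    lag correction disabled both windows are instead centered on the
    reference minimum time.  Pairs containing missing estimates are dropped;
    ``n_points`` reports the pairs actually used.  The correlation is
    reported as ``nan`` when either window is constant.
    """
    tg_ref, v_ref = _resample(ref, cfg.resample_hz)
    tg_est, v_est = _resample(est, cfg.resample_hz)
    half_n = int(round(cfg.half_window_s * cfg.resample_hz))

    i_ref, w_ref = _min_window(tg_ref, v_ref, half_n, "reference")
    i_est_min = int(np.nanargmin(v_est))
    lag = float(tg_est[i_est_min] - tg_ref[i_ref])
    if cfg.allow_lag_correction:
        i_est = i_est_min
    else:
        i_est = int(np.argmin(np.abs(tg_est - tg_ref[i_ref])))
    _, w_est = _min_window(tg_est, v_est, half_n, "estimate", center_idx=i_est)

    ok = np.isfinite(w_ref) & np.isfinite(w_est)
    n = int(ok.sum())
    if n == 0:
        return EvalResult(np.nan, np.nan, lag, 0)
    d = w_est[ok] - w_ref[ok]
    rmse = float(np.sqrt(np.mean(d**2)))
    if n < 2 or np.ptp(w_ref[ok]) == 0 or np.ptp(w_est[ok]) == 0:
        cc = np.nan
    else:
        cc = float(stats.pearsonr(w_ref[ok], w_est[ok])[0])
    return EvalResult(rmse, cc, lag, n)


def aligned_pairs(
    ref: SpO2Series, est: SpO2Series, cfg: EvalConfig = EvalConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """The positionally paired minima-window samples used by the protocol."""
    tg_ref, v_ref = _resample(ref, cfg.resample_hz)
    tg_est, v_est = _resample(est, cfg.resample_hz)
    half_n = int(round(cfg.half_window_s * cfg.resample_hz))
    _, w_ref = _min_window(tg_ref, v_ref, half_n, "reference")
    if cfg.allow_lag_correction:
        _, w_est = _min_window(tg_est, v_est, half_n, "estimate")
    else:
        i_ref = int(np.nanargmin(v_ref))
        i_est = int(np.argmin(np.abs(tg_est - tg_ref[i_ref])))
        _, w_est = _min_window(tg_est, v_est, half_n, "estimate", center_idx=i_est)
    ok = np.isfinite(w_ref) & np.isfinite(w_est)
    return w_ref[ok], w_est[ok]


def bland_altman(ref: np.ndarray, est: np.ndarray) -> BlandAltman:
    """Bland-Altman agreement: bias and 95% limits ``bias +/- 1.96 sd``.

    ``ref`` and ``est`` are paired samples (e.g. from the evaluation
    windows).  Also returns the (mean, difference) point set for plotting.
    """
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("paired series must have equal shape")
    if ref.size < 2:
        raise ValueError("Bland-Altman needs at least 2 paired points")
    diffs = est - ref
    means = (est + ref) / 2.0
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, means, diffs)


def fraction_within(rmses, bound: float = 4.0) -> float:
    """Fraction of per-record RMSEs within an accuracy bound.

    The ISO-style pulse-oximeter criterion asks that the error of 66.6% of
    all data stay within 4%.
    """
    rmses = np.asarray(list(rmses), dtype=float)
    ok = np.isfinite(rmses)
    if not ok.any():
        return np.nan
    return float(np.mean(rmses[ok] <= bound))
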