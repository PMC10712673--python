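"""Modelling objects: :class:`SpO2Model` and :class:`SpO2Results`.

``SpO2Model`` binds a multiband luminance recording to one of the four
windowed estimators; ``fit()`` slides the analysis window across the record
and returns an :class:`SpO2Results` carrying the per-second SpO2 series,
per-window diagnostics, a ``summary()`` table, and evaluation helpers.

>>> record = simulate(SceneConfig(), seed=1)
>>> res = SpO2Model(record.traces, method="m2b").fit()
>>> res.evaluate(record.truth).rmse        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluate import BlandAltman, EvalConfig, EvalResult, align_and_score, aligned_pairs, bland_altman
from .methods import EstimatorSettings, MethodName, estimate_window
from .optics import AbsorptionTable, Band, DEFAULT_BANDS, default_table
from .series import SpO2Series
from .signals import LuminanceTrace, PassBand, window_iter

__all__ = ["SpO2Model", "SpO2Results"]


class SpO2Model:
    """Windowed remote-SpO2 estimator bound to a multiband recording.

    Parameters
    ----------
    traces
        Mapping from band (``"G"``, ``"R"``, ``"NIR"``) to
        :class:`~oxicam.signals.LuminanceTrace`; all bands must share the
        sampling rate and length.
    method
        One of ``conventional``, ``m1``, ``m2a``, ``m2b``.
    table
        Hemoglobin absorption table; defaults to the packaged one.
    win_s, step_s
        Analysis window and step (10 s / 1 s give one estimate per second).
    passband
        Cardiac passband edges in Hz.
    clip
        Clip reported estimates to [0, 100] (raw unclipped values stay
        available on the results object).
    """

    def __init__(
        self,
        traces: dict[Band | str, LuminanceTrace],
        method: MethodName | str = MethodName.m2b,
        table: AbsorptionTable | None = None,
        win_s: float = 10.0,
        step_s: float = 1.0,
        passband: PassBand | tuple[float, float] = (0.7, 3.0),
        filter_order: int = 4,
        edge_trim_frac: float = 0.125,
        amplitude_convention: str = "std",
        amplitude_scale: float = 1.0,
        clip: bool = True,
    ) -> None:
        self.traces = {Band(b): tr for b, tr in traces.items()}
        self.method = MethodName(method)
        missing = [
            b.value for b in self.method.required_bands if b not in self.traces
        ]
        if missing:
            raise KeyError(
                f"method {self.method.value} requires bands {missing}"
            )
        self.table = table or default_table()
        self.win_s = float(win_s)
        self.step_s = float(step_s)
        if not isinstance(passband, PassBand):
            passband = PassBand(*passband)
        self.settings = EstimatorSettings(
            passband=passband,
            filter_order=filter_order,
            edge_trim_frac=edge_trim_frac,
            amplitude_convention=amplitude_convention,
            amplitude_scale=amplitude_scale,
        )
        self.clip = bool(clip)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, fs: float | None = None, **kwargs
    ) -> "SpO2Model":
        """Build a model from a ``time_s,P_G,P_R,P_NIR`` data frame."""
        if fs is None:
            t = np.asarray(df["time_s"], dtype=float)
            dt = np.diff(t)
            if len(dt) == 0 or np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise ValueError("cannot infer fs from a non-uniform time column")
            fs = 1.0 / dt[0]
            t0 = float(t[0])
        else:
            t0 = float(df["time_s"].iloc[0]) if "time_s" in df else 0.0
        traces = {
            band: LuminanceTrace(
                DEFAULT_BANDS[band],
                np.asarray(df[f"P_{band.value}"], dtype=float),
                fs,
                t0,
            )
            for band in (Band.G, Band.R, Band.NIR)
            if f"P_{band.value}" in df
        }
        return cls(traces, **kwargs)

    def fit(self) -> "SpO2Results":
        """Slide the window across the record and estimate SpO2 per step."""
        bands = self.method.required_bands
        traces = [self.traces[b] for b in bands]
        times, raw, diags = [], [], []
        for t_center, wins in window_iter(traces, self.win_s, self.step_s):
            wdict = {b: w for b, w in zip(bands, wins)}
            spo2, diag = estimate_window(
                wdict, self.method, self.table, self.settings
            )
            times.append(t_center)
            raw.append(spo2)
            diags.append(diag)
        raw_arr = np.asarray(raw, dtype=float)
        diagnostics = pd.DataFrame(diags, index=pd.Index(times, name="time_s"))
        return SpO2Results(self, np.asarray(times), raw_arr, diagnostics)


@dataclass
class SpO2Results:
    """Fit output: the SpO2 series plus per-window diagnostics."""

    model: SpO2Model
    times: np.ndarray
    raw_values: np.ndarray
    diagnostics: pd.DataFrame

    @property
    def values(self) -> np.ndarray:
        """Reported estimates (clipped to [0, 100] when the model says so)."""
        if self.model.clip:
            return np.clip(self.raw_values, 0.0, 100.0)
        return self.raw_values

    @property
    def series(self) -> SpO2Series:
        return SpO2Series(self.times, self.values, self.model.method.value)

    @property
    def n_windows(self) -> int:
        return self.times.size

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.raw_values)))

    def evaluate(
        self, ref: SpO2Series, cfg: EvalConfig = EvalConfig()
    ) -> EvalResult:
        """Lag-corrected RMSE/CC against a 1 Hz reference series."""
        return align_and_score(ref, self.series, cfg)

    def bland_altman(
        self, ref: SpO2Series, cfg: EvalConfig = EvalConfig()
    ) -> BlandAltman:
        w_ref, w_est = aligned_pairs(ref, self.series, cfg)
        return bland_altman(w_ref, w_est)

    def summary(self, ref: SpO2Series | None = None) -> str:
        """Plain-text summary table of the fit (and accuracy if a reference is given)."""
        m = self.model
        ok = np.isfinite(self.raw_values)
        lines = [
            "SpO2 estimation results",
            "=" * 47,
            f"{'method':<24}{m.method.value:>23}",
            f"{'window / step (s)':<24}{f'{m.win_s:g} / {m.step_s:g}':>23}",
            f"{'passband (Hz)':<24}"
            f"{f'{m.settings.passband.lo_hz:g}-{m.settings.passband.hi_hz:g}':>23}",
            f"{'windows':<24}{self.n_windows:>23d}",
            f"{'missing windows':<24}{self.n_missing:>23d}",
            f"{'clipped to [0, 100]':<24}{str(m.clip):>23}",
        ]
        if ok.any():
            v = self.values[ok]
            lines += [
                f"{'mean SpO2 (%)':<24}{np.mean(v):>23.2f}",
                f"{'min / max SpO2 (%)':<24}"
                f"{f'{np.min(v):.2f} / {np.max(v):.2f}':>23}",
            ]
        if ref is not None:
            r = self.evaluate(ref)
            lines += [
                "-" * 47,
                f"{'lag-corrected RMSE (%)':<24}{r.rmse:>23.3f}",
                f"{'correlation (CC)':<24}{r.cc:>23.3f}",
                f"{'lag (s)':<24}{r.lag_s:>23.1f}",
                f"{'paired points':<24}{r.n_points:>23d}",
            ]
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot(self, ref: SpO2Series | None = None, ax=None):
        """Plot the estimated series (and reference, if given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        ax.plot(self.times, self.values, label=f"estimate ({self.model.method.value})")
        if ref is not None:
            ax.plot(ref.times, ref.values, "--", label="reference")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("SpO2 (%)")
        ax.legend(frameon=False)
        return ax

    def plot_bland_altman(self, ref: SpO2Series, ax=None):
        import matplotlib.pyplot as plt

        ba = self.bland_altman(ref)
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(ba.means, ba.diffs, s=12)
        for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
        ax.set_xlabel("mean of reference and estimate (%)")
        ax.set_ylabel("estimate - reference (%)")
        return ax
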