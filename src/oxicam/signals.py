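"""Reusable signal operators for video-plethysmography traces.

The operators here are deliberately small and pure: sliding windows, a
zero-phase band-pass around the cardiac band, AC/DC decomposition of the raw
luminance, a sign-invariant amplitude estimator, and covariance-based
principal-component separation.  Estimation methods are composed from these
in :mod:`oxicam.methods`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

from .optics import Band, WavelengthBand, DEFAULT_BANDS

__all__ = [
    "PassBand",
    "LuminanceTrace",
    "PulsatileSignal",
    "window_iter",
    "bandpass",
    "bandpass_log",
    "ac_dc",
    "amplitude",
    "pca_split",
]


@dataclass(frozen=True)
class PassBand:
    """Band-pass edges (Hz) for the heart-rate-related band.

    The default 0.7-3.0 Hz covers resting adult heart rates of 42-180 bpm.
    """

    lo_hz: float = 0.7
    hi_hz: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError(f"require 0 < lo_hz < hi_hz, got {self}")

    def validate_fs(self, fs: float) -> None:
        if self.hi_hz >= fs / 2:
            raise ValueError(
                f"passband upper edge {self.hi_hz} Hz must lie below the "
                f"Nyquist frequency {fs / 2} Hz"
            )


@dataclass
class LuminanceTrace:
    """Mean-ROI luminance of one band sampled at a fixed rate.

    Samples must be strictly positive: the log is taken downstream.
    """

    band: WavelengthBand
    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class PulsatileSignal:
    """Filtered pulsatile absorbance series A_AC for one band or component.

    Sign convention: ``A_AC = -bandpass(log P)``, so an absorbance increase
    (more blood in the path) is positive.
    """

    label: str
    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def window_iter(
    traces: Sequence[LuminanceTrace],
    win_s: float,
    step_s: float,
) -> Iterator[tuple[float, list[LuminanceTrace]]]:
    """Slide an aligned window across a multiband trace set.

    Yields ``(t_center, [trace_window per band])`` for
    ``floor((T - win_s)/step_s) + 1`` windows, where T is the record
    duration.  All bands are windowed identically.
    """
    if step_s <= 0:
        raise ValueError(f"step_s must be positive, got {step_s}")
    ns = {t.n for t in traces}
    fss = {t.fs for t in traces}
    if len(ns) != 1 or len(fss) != 1:
        raise ValueError("all bands must share length and sampling rate")
    (n,), (fs,) = ns, fss
    win_n = int(round(win_s * fs))
    step_n = int(round(step_s * fs))
    if win_n > n:
        raise ValueError(
            f"record of {n / fs:g} s is shorter than one {win_s:g} s window"
        )
    n_windows = (n - win_n) // step_n + 1
    t0 = traces[0].t0
    for k in range(n_windows):
        i = k * step_n
        t_center = t0 + (i + win_n / 2) / fs
        yield t_center, [
            LuminanceTrace(t.band, t.samples[i : i + win_n], fs, t0 + i / fs)
            for t in traces
        ]


def _sos(band: PassBand, fs: float, order: int = 4):
    band.validate_fs(fs)
    return sps.butter(
        order, [band.lo_hz, band.hi_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass(x: np.ndarray, fs: float, band: PassBand, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a raw series.

    Forward-backward filtering preserves inter-band phase relations, on which
    the principal-component separation relies.
    """
    x = np.asarray(x, dtype=float)
    return sps.sosfiltfilt(_sos(band, fs, order), x)


def bandpass_log(
    trace: LuminanceTrace,
    band: PassBand = PassBand(),
    order: int = 4,
) -> PulsatileSignal:
    """Pulsatile absorbance A_AC from a luminance trace.

    Takes the natural log of the trace (turning camera gain, incident
    intensity and melanin absorbance into additive constants), band-passes it
    around the cardiac band (removing those constants together with slow
    drifts), and negates (luminance moves opposite to absorbance).
    """
    if np.any(trace.samples <= 0):
        bad = int(np.argmax(trace.samples <= 0))
        raise ValueError(
            f"nonpositive luminance sample at index {bad} "
            f"({trace.samples[bad]:g}); log-absorbance is undefined"
        )
    filt = bandpass(np.log(trace.samples), trace.fs, band, order)
    return PulsatileSignal(trace.band.label.value, -filt, trace.fs, trace.t0)


def ac_dc(
    trace: LuminanceTrace,
    band: PassBand = PassBand(),
    order: int = 4,
) -> tuple[np.ndarray, float]:
    """AC/BC decomposition of a raw luminance window.

    BC is the window mean of the raw luminance; AC is the zero-phase
    band-pass of the raw luminance (no log).  The conventional estimator
    forms dA = amplitude(AC)/BC, the first-order (Maclaurin) approximation
    of the log-absorbance amplitude.
    """
    if np.any(trace.samples <= 0):
        raise ValueError("luminance window must be strictly positive")
    bc = float(np.mean(trace.samples))
    ac = bandpass(trace.samples, trace.fs, band, order)
    return ac, bc


def amplitude(x: np.ndarray, convention: str = "std", scale: float = 1.0) -> float:
    """Sign-invariant amplitude of a windowed series.

    ``std`` (default) is the sample standard deviation; ``ptp`` is half the
    peak-to-peak range.  Any fixed linear convention cancels in the
    two-wavelength absorbance ratio, so the choice only matters for reported
    per-band amplitudes, never for SpO2.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("amplitude needs at least 2 samples")
    if convention == "std":
        a = float(np.std(x, ddof=1))
    elif convention == "ptp":
        a = float(np.ptp(x)) / 2.0
    else:
        raise ValueError(f"unknown amplitude convention {convention!r}")
    return scale * a


def pca_split(
    signals: Sequence[np.ndarray],
    eig_rtol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Covariance-based principal-component separation of aligned windows.

    Each input series is centered (no variance scaling: unit-variance
    whitening would destroy the absolute amplitude information the
    absorbance ratio needs).  Returns ``(scores, eigenvalues)`` with score
    series in columns ordered by decreasing eigenvalue.  Component sign is
    fixed deterministically (largest-magnitude loading positive) but carries
    no meaning; downstream amplitude estimation is sign-invariant.

    Exactly collinear inputs are legal and yield a zero trailing score
    series; an all-constant input set raises.
    """
    X = np.column_stack([np.asarray(s, dtype=float) for s in signals])
    n, k = X.shape
    if n <= k:
        raise ValueError(f"window length {n} must exceed number of signals {k}")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - 1)
    total = np.trace(cov)
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate covariance: all input signals constant")
    evals, evecs = np.linalg.eigh(cov)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    evals = np.clip(evals, 0.0, None)
    # equal eigenvalues (within tolerance): deterministic order by the index
    # of each component's dominant loading
    for i in range(k - 1):
        if abs(evals[i] - evals[i + 1]) <= eig_rtol * max(evals[0], 1e-300):
            di = int(np.argmax(np.abs(evecs[:, i])))
            dj = int(np.argmax(np.abs(evecs[:, i + 1])))
            if dj < di:
                evecs[:, [i, i + 1]] = evecs[:, [i + 1, i]]
                evals[[i, i + 1]] = evals[[i + 1, i]]
    # deterministic sign: dominant loading positive
    for j in range(k):
        d = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[d, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xc @ evecs
    return scores, evals
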