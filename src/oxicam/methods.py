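"""The four windowed SpO2 estimators.

All four share the same skeleton: estimate the pulsatile absorbance change
``dA`` at the red and NIR bands inside one analysis window, form the ratio
``r = dA(R)/dA(NIR)`` and invert it through the hemoglobin absorption table.
They differ only in how ``dA`` is extracted:

``conventional``
    AC/BC normalization of the raw luminance: ``dA = amplitude(bandpass(P))
    / mean(P)``.  Relies on the first-order Maclaurin approximation
    ``-log(1 - dI/I) ~ dI/I``, which degrades when the bias component is
    small relative to the pulsation.
``m1``
    Log-domain filtering: ``dA = amplitude(bandpass(log P))``.  Exact under
    the Lambert-Beer model; multiplicative gains and slow illumination
    drifts become additive constants or out-of-band terms and are removed
    by the filter.
``m2a``
    Penetration-depth separation: the green band only reaches the dermis,
    so its pulsatile absorbance is (a proxy for) the shallow-layer component
    common to all bands.  PCA of the pair (A_AC(R), A_AC(G)) splits the
    window into a common (shallow) and a residual (deep, arterial)
    component; ``dA(R)`` is the amplitude of the deep component, and
    likewise for (A_AC(NIR), A_AC(G)).
``m2b``
    As m2a, but the shallow reference is first estimated as the dominant
    common component of all three bands, then paired with each of R and NIR.

Component identification in m2a/m2b uses the green band as the anchor: among
the principal components of a pair, the *shallow* component is the one more
correlated with the shallow reference and the *deep* component is the other
one.  When the shallow pulsation dominates (the operating regime of these
methods) this coincides with eigenvalue order (PC1 shallow, PC2 deep); when
the shallow component vanishes the rule degrades gracefully to using the
full band signal instead of a noise component.

Degenerate windows (zero pulsatile amplitude, collinear PCA inputs) yield
``nan`` rather than raising: real recordings have dropout, and evaluation
skips missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .optics import AbsorptionTable, Band, spo2_from_ratio
from .signals import LuminanceTrace, PassBand, ac_dc, bandpass_log, pca_split

__all__ = [
    "MethodName",
    "EstimatorSettings",
    "estimate_window",
    "estimate_conventional",
    "estimate_m1",
    "estimate_m2a",
    "estimate_m2b",
]


class MethodName(str, Enum):
    conventional = "conventional"
    m1 = "m1"
    m2a = "m2a"
    m2b = "m2b"

    @property
    def required_bands(self) -> tuple[Band, ...]:
        if self in (MethodName.conventional, MethodName.m1):
            return (Band.R, Band.NIR)
        return (Band.G, Band.R, Band.NIR)


@dataclass(frozen=True)
class EstimatorSettings:
    """Shared knobs of the windowed estimators.

    edge_trim_frac
        Fraction of the window discarded at each edge before amplitude and
        PCA estimation, absorbing zero-phase filter edge transients.
    amplitude_convention / amplitude_scale
        Reported-amplitude convention.  The constant cancels algebraically
        in the two-band ratio, so it is never applied on the SpO2 path;
        estimates are therefore bit-identical under rescaling.
    """

    passband: PassBand = field(default_factory=PassBand)
    filter_order: int = 4
    edge_trim_frac: float = 0.125
    amplitude_convention: str = "std"
    amplitude_scale: float = 1.0
    #: absorbance-change amplitudes below this are numerical residue of
    #: filtering a constant channel, not pulsation -> missing value
    min_amplitude: float = 1e-9


def _trim(x: np.ndarray, frac: float) -> np.ndarray:
    k = int(len(x) * frac)
    return x[k : len(x) - k] if k > 0 else x


def _amp(x: np.ndarray, settings: EstimatorSettings) -> float:
    """Convention-free amplitude used on the ratio path (see module docs)."""
    if settings.amplitude_convention == "ptp":
        return float(np.ptp(x)) / 2.0
    return float(np.std(x, ddof=1))


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


_CORR_TIE_TOL = 1e-6
# a reference this small relative to the target carries no usable shallow
# information (numerical residue of filtering a constant channel)
_REF_FLOOR = 1e-9


def _deep_component(
    target: np.ndarray, shallow_ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Split ``target`` against a shallow reference; return the deep score.

    Returns ``(deep_scores, eigenvalues, corr_shallow)`` where
    ``corr_shallow`` is the |correlation| of the selected shallow component
    with the reference (a diagnostic of how well the premise held).  A
    vanishing reference means there is no shallow component to remove, and
    the centered target itself is the deep signal.
    """
    if np.std(shallow_ref) < _REF_FLOOR * np.std(target):
        return target - target.mean(), None, 0.0
    scores, evals = pca_split([target, shallow_ref])
    c = [abs(_safe_corr(scores[:, j], shallow_ref)) for j in range(2)]
    if abs(c[0] - c[1]) <= _CORR_TIE_TOL:
        # uninformative reference: keep the dominant component as deep
        deep_j = 0
    else:
        deep_j = int(np.argmin(c))
    return scores[:, deep_j], evals, c[1 - deep_j]


def _ratio_to_spo2(
    amp_r: float, amp_nir: float, table: AbsorptionTable,
    floor: float = 0.0,
) -> tuple[float, float]:
    if not (np.isfinite(amp_r) and np.isfinite(amp_nir)):
        return np.nan, np.nan
    if amp_r <= floor or amp_nir <= floor:
        return np.nan, np.nan
    r = amp_r / amp_nir
    try:
        return spo2_from_ratio(r, table, (Band.R, Band.NIR)), r
    except (ZeroDivisionError, ValueError):
        return np.nan, r


def estimate_conventional(
    windows: dict[Band, LuminanceTrace],
    table: AbsorptionTable,
    settings: EstimatorSettings = EstimatorSettings(),
) -> tuple[float, dict]:
    """Conventional AC/BC ratio-of-ratios estimate for one window."""
    amps = {}
    for band in (Band.R, Band.NIR):
        ac, bc = ac_dc(windows[band], settings.passband, settings.filter_order)
        amps[band] = _amp(_trim(ac, settings.edge_trim_frac), settings) / bc
    spo2, r = _ratio_to_spo2(
        amps[Band.R], amps[Band.NIR], table, settings.min_amplitude
    )
    return spo2, {
        "ratio": r,
        "dA_R": settings.amplitude_scale * amps[Band.R],
        "dA_NIR": settings.amplitude_scale * amps[Band.NIR],
    }


def _pulsatile(
    windows: dict[Band, LuminanceTrace],
    bands: tuple[Band, ...],
    settings: EstimatorSettings,
) -> dict[Band, np.ndarray]:
    out = {}
    for band in bands:
        sig = bandpass_log(windows[band], settings.passband, settings.filter_order)
        out[band] = _trim(sig.samples, settings.edge_trim_frac)
    return out


def estimate_m1(
    windows: dict[Band, LuminanceTrace],
    table: AbsorptionTable,
    settings: EstimatorSettings = EstimatorSettings(),
) -> tuple[float, dict]:
    """Method 1: log-domain band-pass estimate for one window."""
    a = _pulsatile(windows, (Band.R, Band.NIR), settings)
    amp_r = _amp(a[Band.R], settings)
    amp_nir = _amp(a[Band.NIR], settings)
    spo2, r = _ratio_to_spo2(amp_r, amp_nir, table, settings.min_amplitude)
    return spo2, {
        "ratio": r,
        "dA_R": settings.amplitude_scale * amp_r,
        "dA_NIR": settings.amplitude_scale * amp_nir,
    }


def estimate_m2a(
    windows: dict[Band, LuminanceTrace],
    table: AbsorptionTable,
    settings: EstimatorSettings = EstimatorSettings(),
) -> tuple[float, dict]:
    """Method 2A: per-pair PCA depth separation against the green band."""
    a = _pulsatile(windows, (Band.G, Band.R, Band.NIR), settings)
    diag: dict = {}
    amps = {}
    for band in (Band.R, Band.NIR):
        deep, evals, corr = _deep_component(a[band], a[Band.G])
        amps[band] = _amp(deep, settings)
        diag[f"eig_ratio_{band.value}"] = (
            evals[0] / evals[1] if evals is not None and evals[1] > 0 else np.inf
        )
        diag[f"shallow_corr_{band.value}"] = corr
    spo2, r = _ratio_to_spo2(
        amps[Band.R], amps[Band.NIR], table, settings.min_amplitude
    )
    diag.update(
        ratio=r,
        dA_R=settings.amplitude_scale * amps[Band.R],
        dA_NIR=settings.amplitude_scale * amps[Band.NIR],
    )
    return spo2, diag


def estimate_m2b(
    windows: dict[Band, LuminanceTrace],
    table: AbsorptionTable,
    settings: EstimatorSettings = EstimatorSettings(),
) -> tuple[float, dict]:
    """Method 2B: three-band common component, then per-band separation."""
    a = _pulsatile(windows, (Band.G, Band.R, Band.NIR), settings)
    ref_scale = max(np.std(a[Band.R]), np.std(a[Band.NIR]))
    if np.std(a[Band.G]) < _REF_FLOOR * ref_scale:
        # no shallow information anywhere: nothing to separate
        common = np.zeros_like(a[Band.G])
        diag: dict = {"eig_ratio_all": np.inf, "common_index": -1,
                      "common_corr_G": 0.0}
    else:
        scores, evals = pca_split([a[Band.R], a[Band.NIR], a[Band.G]])
        # the shallow reference is the component anchored by the green band
        corrs = [abs(_safe_corr(scores[:, j], a[Band.G])) for j in range(3)]
        best = max(corrs)
        tied = [j for j, c in enumerate(corrs) if best - c <= _CORR_TIE_TOL]
        common_j = tied[-1]  # ties: prefer the lowest-variance candidate
        common = scores[:, common_j]
        diag = {
            "eig_ratio_all": evals[0] / evals[1] if evals[1] > 0 else np.inf,
            "common_index": common_j,
            "common_corr_G": corrs[common_j],
        }
    amps = {}
    for band in (Band.R, Band.NIR):
        deep, ev2, corr = _deep_component(a[band], common)
        amps[band] = _amp(deep, settings)
        diag[f"eig_ratio_{band.value}"] = (
            ev2[0] / ev2[1] if ev2 is not None and ev2[1] > 0 else np.inf
        )
        diag[f"shallow_corr_{band.value}"] = corr
    spo2, r = _ratio_to_spo2(
        amps[Band.R], amps[Band.NIR], table, settings.min_amplitude
    )
    diag.update(
        ratio=r,
        dA_R=settings.amplitude_scale * amps[Band.R],
        dA_NIR=settings.amplitude_scale * amps[Band.NIR],
    )
    return spo2, diag


_DISPATCH = {
    MethodName.conventional: estimate_conventional,
    MethodName.m1: estimate_m1,
    MethodName.m2a: estimate_m2a,
    MethodName.m2b: estimate_m2b,
}


def estimate_window(
    windows: dict[Band, LuminanceTrace],
    method: MethodName | str,
    table: AbsorptionTable,
    settings: EstimatorSettings = EstimatorSettings(),
) -> tuple[float, dict]:
    """Run one estimator on one aligned multiband window.

    Returns ``(spo2_percent_or_nan, diagnostics)``.  The estimate is not
    clipped; clipping to [0, 100] is a reporting decision of the pipeline.
    """
    method = MethodName(method)
    missing = [b.value for b in method.required_bands if b not in windows]
    if missing:
        raise KeyError(f"method {method.value} requires bands {missing}")
    try:
        return _DISPATCH[method](windows, table, settings)
    except ValueError:
        # degenerate window (constant signals etc.) -> missing estimate
        return np.nan, {"ratio": np.nan}
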