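"""Lambert-Beer forward simulator of breath-hold multiband recordings.

The simulator generates mean-ROI luminance traces for the three LED bands
with a known ground-truth SpO2 trajectory, emulating the voluntary-apnea
protocol: a resting baseline around 97% with a smooth transient dip.

Per band ``i`` and time ``t`` the skin absorbance is

    A(i, t) = A_m(i) + A0_static(i) + g(i) p_sh(t)
              + d_i [eps_HbO2(i) c_HbO2(t) + eps_Hb(i) c_Hb(t)]
                    (l + dl p_deep(t))

with the penetration-depth layering d_G = 0, d_R = d_NIR = 1: green light
never reaches the subcutaneous arteries, so the green band carries only the
shallow (dermal capillary) pulsation ``g(i) p_sh(t)`` that is common to all
bands.  The sensor sees

    P(i, t) = k I0(i) (1 + m(t)) exp(-A(i, t)) + ambient_i(t) + noise

where ``m`` is a slow multiplicative motion/illumination drift common to
all bands and ambient light is additive after the skin (it does not pass
through the absorbing layers).

Key assumption (documented limitation): the shallow pulse shares the
cardiac frequency but has a different phase and harmonic mix than the deep
pulse.  Without that linear independence no linear method could separate
the layers, and the premise of the depth-separation methods would be
unrealizable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from . import io as oio
from .optics import AbsorptionTable, Band, WavelengthBand, DEFAULT_BANDS, default_table
from .series import SpO2Series
from .signals import LuminanceTrace

__all__ = ["SceneConfig", "SyntheticRecord", "simulate", "make_fixture_suite"]

_BANDS = (Band.G, Band.R, Band.NIR)


def _per_band(value) -> dict[Band, float]:
    if isinstance(value, dict):
        return {Band(k): float(v) for k, v in value.items()}
    return {b: float(value) for b in _BANDS}


@dataclass
class SceneConfig:
    """Full forward-model parameterization with a ground-truth trajectory.

    Units: absorbances are dimensionless (natural log), path lengths in cm,
    concentrations in mol/L, extinction coefficients in L mol^-1 cm^-1,
    luminances in arbitrary camera counts.

    Defaults describe a realistic resting breath-hold recording: 120 s at
    30 Hz, baseline SpO2 97% dipping to 90%, heart rate 1.1 Hz, deep
    (arterial) pulsatile modulation of 1-2% of the DC luminance, a shallow
    dermal pulsation with about four times the deep variance, a 2% slow
    multiplicative drift, constant additive ambient light and white sensor
    noise.
    """

    fs: float = 30.0
    duration_s: float = 120.0

    # camera and illumination
    gain_k: float = 1.0
    i0: dict[Band, float] = field(default_factory=lambda: _per_band(200.0))

    # static absorbances
    a_melanin: dict[Band, float] = field(
        default_factory=lambda: {Band.G: 0.35, Band.R: 0.22, Band.NIR: 0.12}
    )
    a0_static: dict[Band, float] = field(
        default_factory=lambda: {Band.G: 0.60, Band.R: 0.45, Band.NIR: 0.35}
    )

    # hemodynamics
    c_total: float = 2.3e-3  # mol/L, ~150 g/L hemoglobin
    path_l: float = 0.1  # cm, mean optical path in the deep layer
    delta_l: float = 0.006  # cm, pulsatile path-length amplitude
    hr_hz: float = 1.1
    deep_harmonic: float = 0.3
    deep_harmonic_phase: float = 0.6

    # Shallow (dermal capillary) pulsation: one common time course whose
    # per-band absorbance amplitude follows the hemoglobin extinction mix of
    # capillary blood (taken at ~80% saturation) over a ~0.006 cm pulsatile
    # path, with the green amplitude attenuated (factor ~0.4) for the
    # shallower effective green path.  At the red band this puts the shallow
    # variance at about four times the deep variance.
    shallow_gain: dict[Band, float] = field(
        default_factory=lambda: {Band.G: 0.13, Band.R: 0.021, Band.NIR: 0.0136}
    )
    shallow_phase: float = 0.3
    shallow_harmonic: float = 0.15
    shallow_harmonic_phase: float = 1.2

    # nuisance terms
    motion_std: float = 0.02
    motion_bw_hz: float = 0.15
    ambient: dict[Band, float] = field(default_factory=lambda: _per_band(8.0))
    ambient_flicker_amp: float = 0.0
    ambient_flicker_hz: float = 0.0
    noise_sd: float = 0.15
    quant_step: float | None = None

    # ground-truth SpO2 trajectory (smooth Gaussian-shaped dip)
    baseline_spo2: float = 97.0
    dip_depth: float = 7.0
    dip_center_s: float = 70.0
    dip_width_s: float = 12.0

    table: AbsorptionTable = field(default_factory=default_table)

    def __post_init__(self) -> None:
        self.i0 = _per_band(self.i0)
        self.a_melanin = _per_band(self.a_melanin)
        self.a0_static = _per_band(self.a0_static)
        self.shallow_gain = _per_band(self.shallow_gain)
        self.ambient = _per_band(self.ambient)
        for d in (self.a_melanin, self.a0_static, self.shallow_gain, self.ambient):
            if any(v < 0 for v in d.values()):
                raise ValueError("absorbances and ambient levels must be >= 0")
        if not 0 <= self.baseline_spo2 - self.dip_depth <= self.baseline_spo2 <= 100:
            raise ValueError("SpO2 trajectory must stay within [0, 100]")
        if self.fs <= 2 * 2 * self.hr_hz:
            raise ValueError("fs must exceed twice the highest cardiac harmonic")

    def trajectory(self, t: np.ndarray) -> np.ndarray:
        """Ground-truth SpO2 (percent) at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        return self.baseline_spo2 - self.dip_depth * np.exp(
            -((t - self.dip_center_s) ** 2) / (2 * self.dip_width_s**2)
        )

    def replace(self, **changes) -> "SceneConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("i0", "a_melanin", "a0_static", "shallow_gain", "ambient"):
            d[key] = {b.value: v for b, v in getattr(self, key).items()}
        d["table"] = {
            b.value: [self.table.eps_hbo2(b), self.table.eps_hb(b)]
            for b in self.table.bands
        }
        return d


@dataclass
class SyntheticRecord:
    """Simulator output: traces, 1 Hz truth, and the generating config."""

    traces: dict[Band, LuminanceTrace]
    truth: SpO2Series
    config: SceneConfig
    seed: int | None = None
    absorbance: dict[Band, np.ndarray] | None = None


def _cardiac(t: np.ndarray, f: float, h: float, hp: float, phase: float = 0.0):
    return np.sin(2 * np.pi * f * t + phase) + h * np.sin(
        4 * np.pi * f * t + phase + hp
    )


def _motion(n: int, fs: float, std: float, bw: float, rng: np.random.Generator):
    if std <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = sps.butter(2, bw, btype="low", fs=fs, output="sos")
    m = sps.sosfiltfilt(sos, white)
    s = np.std(m)
    return m * (std / s) if s > 0 else np.zeros(n)


def simulate(config: SceneConfig, seed: int | None = 0) -> SyntheticRecord:
    """Generate one synthetic breath-hold record, reproducible from ``seed``."""
    cfg = config
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    rng = np.random.default_rng(seed)

    s = cfg.trajectory(t)
    c_o2 = cfg.c_total * s / 100.0
    c_hb = cfg.c_total * (1.0 - s / 100.0)

    p_deep = _cardiac(t, cfg.hr_hz, cfg.deep_harmonic, cfg.deep_harmonic_phase)
    p_sh = _cardiac(
        t,
        cfg.hr_hz,
        cfg.shallow_harmonic,
        cfg.shallow_harmonic_phase,
        phase=cfg.shallow_phase,
    )
    m = _motion(n, cfg.fs, cfg.motion_std, cfg.motion_bw_hz, rng)

    traces: dict[Band, LuminanceTrace] = {}
    absorb: dict[Band, np.ndarray] = {}
    for band in _BANDS:
        depth = 0.0 if band is Band.G else 1.0
        eps_mix = cfg.table.eps_hbo2(band) * c_o2 + cfg.table.eps_hb(band) * c_hb
        a = (
            cfg.a_melanin[band]
            + cfg.a0_static[band]
            + cfg.shallow_gain[band] * p_sh
            + depth * eps_mix * (cfg.path_l + cfg.delta_l * p_deep)
        )
        absorb[band] = a
        amb = cfg.ambient[band] * (
            1.0
            + cfg.ambient_flicker_amp
            * np.sin(2 * np.pi * cfg.ambient_flicker_hz * t)
        )
        p = cfg.gain_k * cfg.i0[band] * (1.0 + m) * np.exp(-a) + amb
        if cfg.noise_sd > 0:
            p = p + cfg.noise_sd * rng.standard_normal(n)
        if cfg.quant_step:
            p = np.round(p / cfg.quant_step) * cfg.quant_step
        if np.any(p <= 0):
            raise ValueError(
                "simulated luminance went nonpositive; reduce noise/ambient "
                "or raise the illumination level"
            )
        traces[band] = LuminanceTrace(DEFAULT_BANDS[band], p, cfg.fs)

    t_truth = np.arange(int(np.floor(cfg.duration_s)))
    truth = SpO2Series(t_truth.astype(float), cfg.trajectory(t_truth), "truth")
    return SyntheticRecord(traces, truth, cfg, seed, absorb)


def render_frames(
    record: SyntheticRecord,
    shape: tuple[int, int] = (64, 64),
    spatial_noise_sd: float = 0.0,
    seed: int | None = 0,
) -> tuple[dict[Band, np.ndarray], np.ndarray]:
    """Expand a record's traces into small per-band frame stacks.

    Each frame holds the band's trace value inside an elliptical face ROI
    (plus optional zero-mean spatial shot noise) and half that value
    outside.  Returns ``(stacks, roi_mask)`` so that
    :func:`oxicam.io.mean_roi_luminance` applied to the stack and mask
    recovers the original trace up to the spatial noise average.
    """
    h, w = shape
    yy, xx = np.mgrid[:h, :w]
    mask = ((yy - h / 2) / (0.4 * h)) ** 2 + ((xx - w / 2) / (0.3 * w)) ** 2 <= 1.0
    rng = np.random.default_rng(seed)
    stacks = {}
    for band, tr in record.traces.items():
        base = np.where(mask, 1.0, 0.5)[None] * tr.samples[:, None, None]
        if spatial_noise_sd > 0:
            noise = spatial_noise_sd * rng.standard_normal(base.shape)
            base = np.clip(base + noise, 1e-6, None)
        stacks[band] = base
    return stacks, mask


_FIXTURE_SCENES: dict[str, dict] = {
    "deep_only": dict(
        shallow_gain=0.0, motion_std=0.0, ambient=0.0, noise_sd=0.0
    ),
    "shallow_dominant": dict(motion_std=0.0, ambient=0.0, noise_sd=0.0),
    "ambient_light": dict(shallow_gain=0.0, motion_std=0.0, noise_sd=0.05),
    "motion_drift": dict(shallow_gain=0.0, ambient=0.0, noise_sd=0.05),
    "desaturation_dip": dict(),  # everything on: the full default scene
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(out_dir, base_config: SceneConfig | None = None, seed: int = 0):
    """Write the canonical five-scene fixture family with a manifest.

    Scenes: noise-free deep-only, shallow-dominant, ambient-light,
    motion-drift, and the full default desaturation dip.  Each scene yields
    one trace file and one truth file; the manifest records configs, seeds
    and checksums so any scene can be regenerated bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = base_config or SceneConfig()
    manifest: dict = {"seed": seed, "scenes": {}}
    for i, (name, changes) in enumerate(_FIXTURE_SCENES.items()):
        scene_seed = seed + i
        cfg = base.replace(**changes)
        rec = simulate(cfg, scene_seed)
        trace_path = out / f"{name}_traces.csv"
        truth_path = out / f"{name}_truth.csv"
        oio.write_trace(trace_path, rec.traces)
        oio.write_series(truth_path, rec.truth)
        manifest["scenes"][name] = {
            "seed": scene_seed,
            "config": cfg.to_dict(),
            "files": {
                trace_path.name: _sha256(trace_path),
                truth_path.name: _sha256(truth_path),
            },
        }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
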