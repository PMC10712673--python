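import numpy as np
import pytest

from conftest import clean_scene, fit_values
from oxicam import SpO2Model
from oxicam.methods import EstimatorSettings, MethodName, estimate_window
from oxicam.optics import Band
from oxicam.signals import LuminanceTrace
from oxicam.synth import SceneConfig, simulate


def window_dict(record, bands=(Band.G, Band.R, Band.NIR), n=300):
    return {b: LuminanceTrace(record.traces[b].band,
                              record.traces[b].samples[:n],
                              record.traces[b].fs) for b in bands}


class TestNoiseFreeRecovery:
    @pytest.mark.parametrize("method", list(MethodName))
    def test_deep_only_scene_recovered(self, method):
        rec = simulate(clean_scene(baseline_spo2=97.0), 1)
        v = fit_values(rec, method)
        assert np.all(np.isfinite(v))
        assert np.max(np.abs(v - 97.0)) < 1.5
        # the log method avoids the Maclaurin approximation entirely
        if method is MethodName.m1:
            assert np.max(np.abs(v - 97.0)) < 0.5

    def test_conventional_degrades_when_dc_shrinks_with_ac_held(self):
        # DC reduced 10x with the absolute pulsatile luminance swing held:
        # the first-order -log(1-x) ~ x approximation error grows
        hi = simulate(clean_scene(), 1)
        lo = simulate(clean_scene(i0=20.0, delta_l=0.06), 1)
        err_hi = np.nanmax(np.abs(fit_values(hi, "conventional") - 97.0))
        err_lo = np.nanmax(np.abs(fit_values(lo, "conventional") - 97.0))
        assert err_lo > err_hi

    def test_identical_band_windows_give_unit_ratio_value(self, table):
        rec = simulate(clean_scene(), 1)
        w = window_dict(rec)
        w[Band.NIR] = w[Band.R]  # both bands see the same luminance
        spo2, diag = estimate_window(w, "conventional", table)
        assert diag["ratio"] == pytest.approx(1.0, abs=1e-12)
        e_hb_r, e_hb_n = table.eps_hb(Band.R), table.eps_hb(Band.NIR)
        e_o_r, e_o_n = table.eps_hbo2(Band.R), table.eps_hbo2(Band.NIR)
        expected = 100 * (e_hb_r - e_hb_n) / (e_hb_r - e_o_r + e_o_n - e_hb_n)
        assert spo2 == pytest.approx(expected, rel=1e-9)


class TestInvariances:
    @pytest.mark.parametrize("method", list(MethodName))
    def test_per_band_gain_invariance(self, method, table):
        rec = simulate(SceneConfig(duration_s=30.0), 5)
        w = window_dict(rec)
        scaled = {
            b: LuminanceTrace(t.band, t.samples * g, t.fs)
            for (b, t), g in zip(w.items(), (2.0, 3.7, 0.4))
        }
        s0, _ = estimate_window(w, method, table)
        s1, _ = estimate_window(scaled, method, table)
        assert s1 == pytest.approx(s0, abs=1e-7)

    def test_m1_immune_to_common_multiplicative_drift(self):
        base = simulate(clean_scene(), 2)
        t = np.arange(base.traces[Band.R].n) / 30.0
        drift = np.exp(0.2 * np.sin(2 * np.pi * 0.05 * t))
        drifted = type(base)(
            traces={
                b: LuminanceTrace(tr.band, tr.samples * drift, tr.fs)
                for b, tr in base.traces.items()
            },
            truth=base.truth,
            config=base.config,
        )
        v0 = fit_values(base, "m1")
        v1 = fit_values(drifted, "m1")
        assert np.nanmax(np.abs(v1 - v0)) < 0.01 * 97

    def test_determinism(self, table):
        rec = simulate(SceneConfig(duration_s=30.0), 9)
        w = window_dict(rec)
        for method in MethodName:
            a, _ = estimate_window(w, method, table)
            b, _ = estimate_window(w, method, table)
            assert a == b or (np.isnan(a) and np.isnan(b))


class TestDepthSeparation:
    def test_m2a_beats_m1_under_shallow_contamination(self):
        # the dermal pulsation is common-mode: the band-pass cannot remove
        # it, the green-anchored PCA can
        errs = {"m1": [], "m2a": [], "m2b": []}
        for seed in range(1, 7):
            rec = simulate(
                SceneConfig(motion_std=0.0, ambient=0.0, dip_depth=0.0,
                            duration_s=60.0),
                seed,
            )
            for m in errs:
                errs[m].append(np.nanmean(np.abs(fit_values(rec, m) - 97.0)))
        assert np.mean(errs["m2a"]) < np.mean(errs["m1"])
        assert np.mean(errs["m2b"]) < np.mean(errs["m1"])

    @pytest.mark.parametrize("method", ["m2a", "m2b"])
    def test_zero_shallow_scene_recovered(self, method):
        rec = simulate(clean_scene(noise_sd=0.02), 4)
        v = fit_values(rec, method)
        finite = np.isfinite(v)
        assert finite.mean() > 0.9
        assert np.nanmax(np.abs(v[finite] - 97.0)) < 1.5

    def test_m2a_degenerate_when_green_equals_red(self, table):
        rec = simulate(SceneConfig(duration_s=30.0), 6)
        w = window_dict(rec)
        w[Band.G] = w[Band.R]
        spo2, _ = estimate_window(w, "m2a", table)
        assert np.isnan(spo2)

    def test_m2b_degenerate_when_all_bands_proportional(self, table):
        rec = simulate(clean_scene(duration_s=30.0), 7)
        r = rec.traces[Band.R]
        w = {
            Band.R: r,
            Band.NIR: LuminanceTrace(rec.traces[Band.NIR].band, 2.0 * r.samples, r.fs),
            Band.G: LuminanceTrace(rec.traces[Band.G].band, 0.5 * r.samples, r.fs),
        }
        w = {b: LuminanceTrace(t.band, t.samples[:300], t.fs) for b, t in w.items()}
        spo2, _ = estimate_window(w, "m2b", table)
        assert np.isnan(spo2)

    def test_eigenvalue_diagnostics_surfaced(self):
        rec = simulate(SceneConfig(duration_s=30.0), 8)
        res = SpO2Model(rec.traces, method="m2a").fit()
        assert {"eig_ratio_R", "eig_ratio_NIR"} <= set(res.diagnostics.columns)
        assert (res.diagnostics["eig_ratio_R"] > 1).all()


class TestMissingPolicy:
    def test_missing_band_raises(self, table):
        rec = simulate(SceneConfig(duration_s=30.0), 10)
        w = window_dict(rec, bands=(Band.R, Band.NIR))
        with pytest.raises(KeyError, match="G"):
            estimate_window(w, "m2a", table)

    def test_constant_windows_yield_missing_not_error(self, table):
        rec = simulate(clean_scene(delta_l=0.0, duration_s=30.0), 11)
        w = window_dict(rec)
        for method in MethodName:
            spo2, _ = estimate_window(w, method, table)
            assert np.isnan(spo2)
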