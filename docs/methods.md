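# Methods

## Optical model and SpO2 inversion

Skin-reflected intensity at a narrow band centered on `λ` follows
Lambert–Beer: `I(λ) = I0(λ) exp{−A(λ)}` with total absorbance
`A = A_m + A0 + {ε_HbO2 c_HbO2 + ε_Hb c_Hb} l` (melanin, static dermis,
and hemoglobin over the mean optical path `l`). Heart pulsation modulates
the path by `Δl`, so the pulsatile absorbance is
`ΔA(λ) = {ε_HbO2 c_HbO2 + ε_Hb c_Hb} Δl`. The ratio of two bands removes
`Δl` and the total hemoglobin concentration, leaving a one-parameter family
in the saturation fraction, inverted in closed form (see README). The
optics layer never clips the inversion output; clipping to [0, 100] is a
reporting decision made by the model object (flag `clip`, default on),
keeping the math layer exactly invertible for testing. An inversion
denominator below `1e-12` relative to the numerator scale raises rather
than returning an unbounded value; with a physically shaped table (ε_Hb >
ε_HbO2 at red, the reverse at NIR) the denominator cannot vanish for any
positive ratio.

The shipped absorption table (`oxicam/data/absorption_table.tsv`) carries
the standard OMLC/Prahl hemoglobin extinction values at 524/630/850 nm in
L mol⁻¹ cm⁻¹. Only the per-band ratios and differences matter: the
round-trip identity `invert(forward(s)) = s` holds for any valid table, so
results do not depend on which published compilation is used.

## Windowed estimators

All estimators share a 10 s analysis window stepped by 1 s (one estimate
per second, timestamped at the window center), a 4th-order Butterworth
band-pass applied forward–backward (zero phase, preserving the inter-band
phase relations on which PCA separation relies), and a default 0.7–3.0 Hz
passband covering resting adult heart rates (42–180 bpm). One eighth of
the window is discarded at each edge before amplitude estimation to absorb
filter edge transients (configurable).

The amplitude of a pulsatile series is its sample standard deviation —
robust, sign-invariant, and any fixed linear convention cancels in the
two-band ratio. For that reason the convention constant is never applied
on the ratio path (it would only inject last-ulp rounding noise); it scales
the reported per-band amplitudes in the diagnostics table. Half
peak-to-peak is available as an alternative convention for sensitivity
analysis. Amplitudes below `1e-9` absorbance units are numerical residue
of filtering a constant channel and yield a missing window rather than a
garbage ratio; missing windows are reported as NaN and skipped by the
evaluator, with the count surfaced in `summary()`.

PCA is covariance-based (centering only): unit-variance scaling would
destroy the absolute amplitude information the absorbance ratio needs.
Scores are ordered by decreasing eigenvalue with a deterministic
tie-break (dominant-loading index) and deterministic sign; eigenvalue
ratios of every PCA stage are surfaced in the diagnostics.

### Component identification in the depth-separation methods

The separation premise is that the shallow (dermal capillary) pulsation is
a single time course common to all three bands, while only red and NIR
carry the deep arterial signal. In the usual operating regime the shallow
component dominates and appears as PC1, the deep residual as PC2. When the
shallow component is weak or absent, variance ordering misassigns the
components, so each PCA stage identifies the *shallow* component as the
score most correlated with the green-band signal (the band that physically
carries only shallow information) and takes the other score as deep. Under
shallow dominance this coincides exactly with the PC1/PC2 assignment; with
a vanishing green signal (std below 1e-9 of the target's) there is nothing
to separate and the band signal itself is the deep component. This keeps
the estimators well-defined across the whole range of shallow-to-deep
ratios instead of failing on weakly perfused recordings.

### A structural note on the three-band variant (m2b)

Any second-stage reference that contains an admixture of the deep signal
causes PCA to subtract deep content asymmetrically from the red and NIR
bands, biasing the ratio. The three-band first stage necessarily mixes
some deep signal into its common component (its loading vector cannot be
orthogonal to both deep-carrying bands), so under this forward model m2b
carries a small positive bias relative to m2a, shrinking quadratically as
the green band's shallow amplitude grows relative to red/NIR. With the
default scene this bias is a few tenths of a percent SpO2. The pairwise
method m2a, whose green-band reference is deep-free by construction, is
the accuracy ceiling of the family under this model.

## Forward simulator

`simulate(SceneConfig, seed)` generates per-band mean-ROI luminance traces
with known truth. Per band `i`:

    A(i,t) = A_m(i) + A0_static(i) + g(i)·p_sh(t)
             + δ_i {ε_HbO2(i) c_HbO2(t) + ε_Hb(i) c_Hb(t)} (l + Δl·p_deep(t))
    P(i,t) = k·I0(i)·(1 + m(t))·exp(−A(i,t)) + ambient_i(t) + noise

with penetration layering δ_G = 0, δ_R = δ_NIR = 1. Each band is generated
monochromatically at its LED center (an idealized delta spectral response).

Defaults and rationale:

- `fs` 30 Hz, `duration_s` 120 s; heart rate 1.1 Hz with one harmonic.
- Total hemoglobin `c_total` 2.3 mmol/L (≈150 g/L), mean deep path `l`
  0.1 cm, pulsatile path `Δl` 0.006 cm — giving a deep AC/DC of ≈1–1.5%,
  typical rPPG perfusion.
- Trajectory: baseline 97% (healthy resting range 96–98%) with a smooth
  Gaussian-shaped dip to 90% centered at 70 s (width 12 s), emulating a
  voluntary breath-hold; single minimum by construction.
- Shallow pulsation: same cardiac frequency as the deep pulse but phase
  shifted (0.3 rad) with a different harmonic mix — without this linear
  independence no linear method could separate the layers (the simulator's
  key assumption). Per-band gains follow the extinction mix of capillary
  blood at ~80% saturation over a 0.006 cm path, green attenuated by ~0.4
  for its shallower effective path: G 0.13, R 0.021, NIR 0.0136. At the
  red band this puts shallow variance at ≈4× deep variance. Because
  capillary saturation differs from arterial, the shallow contamination
  genuinely biases ratio-based estimators (by several percent SpO2 for the
  band-pass methods), which is what the depth-separation methods remove.
- Motion/illumination drift: multiplicative, common to all bands, filtered
  white noise below 0.15 Hz with 2% standard deviation.
- Ambient light: additive after the skin (it does not traverse the
  absorbing layers), 8 luminance counts per band (≈10% of DC); optional
  sinusoidal flicker, off by default. Sensor noise: white, sd 0.15 counts.
  Optional quantization step.

What the simulator does **not** emulate: photon-transport scattering and
pathlength-factor corrections (plain Lambert–Beer only), face geometry,
specular reflection, ROI displacement (motion enters only as a common
multiplicative drift), skin-tone variation, and band-specific artifacts in
the green channel. Passing tests therefore demonstrate correctness of the
estimators under the stated optical model, not performance on real video.
In particular, two findings are structural to this model family and should
not be read as statements about real recordings: (i) the conventional
AC/BC estimator and the log-domain estimator coincide to first order under
any additive ambient or slow multiplicative contamination (their
difference is the exponential's curvature, O((AC/DC)²)), and (ii) m2b
cannot outperform m2a (see above). Real-data differences between these
methods must arise from effects outside this model.

## Evaluation protocol

Desaturation reaches different body sites with different circulatory
delays, so reference (fingertip) and estimated (face) series are aligned
on their desaturation minima before scoring: each series contributes the
15 s before and after its own global minimum (earliest sample if tied —
breath-hold records have a single dip by design), samples are paired
positionally on a 1 Hz grid (linear interpolation for other rates; grid
points with no finite source sample within 0.75 steps stay missing), and
RMSE plus Pearson correlation are computed over the pairs. The recovered
lag (estimate minus reference minimum time) is reported; with lag
correction disabled both windows are centered on the reference minimum.
Pairs with missing estimates are dropped and the pair count is reported.
The 4% RMSE working target follows the pulse-oximeter essential-performance
convention (error of 66.6% of data within 4%) together with the 92%
clinical abnormality threshold; `fraction_within` computes the
share-within-bound statistic over an ensemble of per-record RMSEs.
Bland–Altman agreement uses bias ± 1.96·sd of the paired differences and
returns the (mean, difference) point set for plotting. Per-record RMSEs
are averaged across the ensemble (reported with their standard deviation)
rather than pooling all windows, so between-record variability stays
visible.

## Problem sizes

The default study conditions are 120 s records at 30 Hz (111 windows per
record) and 20-seed ensembles; the full test suite and the acceptance
script each run in about a minute on one CPU at these sizes.

## Known limitations

- The component-identification rule anchors on the green band; recordings
  where the green channel carries band-specific artifacts uncorrelated
  with the dermal pulsation would mislead it (diagnostics expose the
  correlation and eigenvalue ratios to detect this).
- The conventional estimator's documented weakness (first-order
  approximation error) only becomes material at AC/DC well above typical
  perfusion; at 1–2% it is sub-0.1% SpO2.
- Estimates outside [0, 100] are clipped by default before evaluation;
  the flag exposes the unclipped series since the right choice for
  downstream statistics is not obvious.
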