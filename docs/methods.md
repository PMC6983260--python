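# Methods

## The measurement problem

A fluorescence immunochromatographic (lateral-flow) strip carries two
reagent lines: the test (T) line, whose bound fluorophore tracks the analyte
concentration, and the control (C) line, which captures excess label on
every run. A camera-based reader excites the strip with a UV LED, images the
emitted fluorescence, and reports the ratio of the two line intensities.

The readout rests on one identity. Line radiance follows the fluorometric
proportionality `I = k_f · C · i_x` (lumped gain `k_f`, fluorophore
concentration `C`, excitation current `i_x`), and the sensor integrates
radiance over the exposure time `t` (photometric exposure `H = E·t`). The
ratio of the two line exposures is therefore

    H_T / H_C = (k_f · C_T · i_x · t) / (k_f · C_C · i_x · t) = C_T / C_C,

independent of both exposure time and excitation current. This is what
makes exposure-time control legitimate: the reader can move the operating
point of an 8-bit sensor up and down the exposure axis to keep both lines
inside its dynamic range without changing the quantity being measured.

## Sensor model

The simulated camera is linear with a dark offset:

    gray = clip(round(dark + gain · radiance · t + ε), 0, 2^bits − 1)

with defaults `dark = 3.480` gray, `gain = 0.547` gray per (radiance·ms) at
unit reference radiance, 8 bits, and a 400 ms linear limit — i.e. the
reference response `G = 0.547·t + 3.480`. Beyond 400 ms the simulator
applies a smooth logarithmic roll-off (continuous value and slope at the
knee); the controller must never request such exposures, and the roll-off
exists so that violating the bound is observable in tests. Rounding is
half-away-from-zero, chosen so the dark level quantizes reproducibly to 3.

Noise has two parts: Gaussian read noise (default σ = 1 gray) added before
quantization, and salt-and-pepper impulse noise (default probability 0.002
per pixel) applied after it. The impulse component exists specifically to
exercise the morphological filter.

## Synthetic assay

A strip scene is a uniform membrane background (default radiance 0.02) plus
two full-height rectangular line bands centred at 1/4 and 3/4 of a 200×80 px
frame. The C-line fluorophore load is fixed (0.8 concentration units); the
T-line load is `C_C · (0.023·x + 0.081)` for analyte concentration `x` in
µg/mL, clamped at zero — i.e. the reference dose–response line is the
simulator's ground truth, so the reader is correct exactly when it returns
`0.023·x + 0.081`.

The operating point is deliberately calibrated to the study regime: with the
C-line signal at ~43.8 gray under the fixed 100 ms protocol, the T-line
characteristic is 4.53 gray at 0.98 µg/mL (below the 5-gray validity floor),
5.51 at 1.95 (just valid), 129 at 125 (valid), and clips the sensor at 256
µg/mL and above. The fixed protocol therefore reads 1.95–125 µg/mL and the
controller must recover the rest. These values follow in closed form from
the sensor line and the dose–response map; they were fixed before any
end-to-end run.

Band half-width defaults to 18 px (the band fills ~37% of its image half).
This is not cosmetic: the entropy-based threshold criterion balances the
partial entropies of the two histogram classes, so the foreground must carry
an entropy share comparable to the background's for the selected threshold
to fall in the gap between the background and band modes (see below). Very
thin lines in a large empty frame push the criterion's optimum into the
background distribution.

What the generator does **not** emulate: optics (PSF, filter spectra,
vignetting), illumination non-uniformity, membrane texture, photobleaching
kinetics, and the high-dose hook effect of real immunoassays. Passing tests
therefore demonstrate the mechanics of segmentation, quantification and
exposure control under an idealized planar scene — not wet-lab performance.
The hook effect is why the real assay returns no reading at 1024 µg/mL
while the simulator, whose dose–response map is linear by construction,
still produces a valid (and correct) ratio there.

## Denoising and segmentation

The captured image is filtered by a grayscale morphological opening followed
by closing with one 3×3 square structuring element — opening removes bright
impulse outliers and edge burrs, closing fills dark pinholes and short
breaks. The image is then split at `floor(width/2)` and each half is
thresholded independently, since the two lines can differ in brightness by
more than an order of magnitude.

Threshold selection maximizes, over all candidate thresholds `t` leaving
both classes non-empty,

    J(t) = (H_A−H_0)² (H_B−H_0)² / ((H_A−H_0)² + (H_B−H_0)²)²,

where `H_A`, `H_B` are the plain partial entropy sums `−Σ p_i log₂ p_i`
over the two gray ranges and `H_0` the whole-image entropy. Because
`H_A + H_B = H_0` identically, `J` reduces to a function that peaks where
`H_A ≈ H_B`: the criterion selects the split that balances the entropy mass.
`J ≤ 1/4` everywhere (AM–GM). Numerical conventions: `0·log₂0 = 0`;
candidates with a zero denominator are skipped; ties break toward the lowest
threshold; a single-occupied-bin histogram raises a degenerate-segmentation
error rather than returning a threshold. The criterion depends only on the
histogram, so it is exactly shift-invariant and approximately invariant
under linear contrast stretches (integer re-binning breaks exactness).

Foreground is gray strictly above the threshold (fluorescent lines are
bright on a dark membrane).

## Feature extraction

The entropy balance places the threshold *near* the background–band gap but
its exact position can flip a small histogram bin between classes, and which
side of the gap it lands on varies with noise. Feature extraction therefore
reduces the threshold mask to the line band explicitly before taking means
— a reagent line spans the full height of the frame, so the band is the
largest contiguous run of columns that are majority-foreground, taken
full-height. Two further numerical choices keep the region means unbiased:

- a 2-column guard zone on each side of the band boundary is excluded from
  both the line and background means, because the morphological filter
  mixes plateau and background values there;
- means are computed from the **raw** pixels, not the filtered ones. The
  open/close filter imprints a value-dependent bias of order −0.8σ on noisy
  regions, and the residual region-to-region variation of that bias (~0.1
  gray) is large enough to distort a T/C ratio of ~12 by more than the
  acceptance tolerance. The filtered image instead serves as the impulse
  detector: raw pixels deviating from it by more than 10 gray are excluded
  as outliers.

The characteristic value of a line is `mean_fg − mean_bg`, floored at 0;
background subtraction removes the additive dark offset and membrane
contribution, which would otherwise break the exposure cancellation. The
T/C ratio is formed per the configured layout (default: T left). A reading
is invalid when either line region is saturated beyond 5% of its pixels or
either characteristic falls below the 5-gray minimum-signal floor — the
counterpart of a real reader's "no result" output.

## Automatic exposure-range adjustment

The controller drives the mean gray `G` of the brighter line (so that
neither line clips) to a target `G_M = 230` via the proportional rule

    t_next = clamp(((G_M − dark) / (G − dark)) · t, 1 ms, 400 ms),

which is exact in one step under linearity; dark-level subtraction is what
makes `G ∝ t` hold. Saturated captures (clipped `G` would make the ratio
step overshoot) halve the exposure instead; degenerate captures with no
detectable line double it, seeking signal. The loop stops on `|G − G_M| ≤
10` gray (converged), on hitting a bound it cannot leave (`below_range` /
`above_range`), or after 8 iterations (noise can hold `|G − G_M|` above any
tolerance indefinitely). On noiseless in-range scenes it converges in at
most 3 captures; the exposure never exceeds the 400 ms linear limit. The
final capture is then quantified as usual; validity is decided by the
quantification stage, so a `below_range` outcome (target gray unreachable
at 400 ms) can still carry a perfectly valid reading.

## Calibration and evaluation

Dose–response and sensor lines are ordinary least squares fits; `R²` is the
coefficient of determination `1 − SS_res/SS_tot` of the OLS line (not a
forced-origin variant). Coefficients are compared to reference values at
3-decimal precision, matching how they are printed; note that OLS on the
packaged 10-point dilution table yields `R² = 0.9989…`, which equals the
published 0.999 only at that printed precision — the original fit was made
on unrounded instrument readings that are not available.

The detection range of a protocol is the span of tested concentrations with
valid readings. The reference-reader comparison fits device readings
against reference readings on overlapping valid concentrations; optionally
the reference is first extended linearly (regressed on concentration over
its valid range and extrapolated to the device grid). The published
description of that extension is ambiguous, so the comparison's `R²` is
reported but not treated as a reproduction target.

## Test design notes

- **Exposure-invariance test scene.** With noiseless constant-plateau bands,
  8-bit rounding contributes up to ±0.5 gray per region mean — at 25 ms,
  where the dim line is ~7 gray, that alone is a ~7% ratio error that has
  nothing to do with exposure dependence. The invariance test therefore
  uses a dark-background scene whose band signals are 0.28 and 0.56 gray/ms
  — exact multiples of the gray quantum on the 25 ms exposure grid — so
  rounding cancels in the background-subtracted characteristics and the
  identity is tested in isolation. A separate test covers noise-dithered
  scenes at the same tolerance.
- **Problem sizes.** All simulations use the 200×80 px default frame and the
  11-point dilution grid; the brute-force threshold oracle runs on
  histograms of ≤16 levels, where exhaustive scalar evaluation is exact and
  fast.
- **Determinism.** Every stochastic component draws from a seeded generator;
  a capture with the same scene, camera, exposure and seed is bit-identical.
  The controller derives per-iteration streams from the camera seed.

## Known limitations

- The entropy-balance threshold needs the line band to occupy a substantial
  fraction of its half-image; the defaults guarantee this, but applying the
  reader to frames where the lines are tiny would require cropping a region
  of interest around each line first.
- Saturation handling assumes the brighter line saturates first, which holds
  for uniform illumination but not necessarily under strong vignetting.
- The simulator's dose–response is linear by construction; none of the
  nonlinear phenomena of real strips (hook effect, membrane variability,
  line inhomogeneity) are represented, and results on real captures should
  be validated against a reference instrument.
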