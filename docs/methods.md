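# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `barriersense`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Calibration model

Mean ROI pixel intensity versus tracer concentration is modelled by the
four-parameter logistic (4PL) response

    F(x) = d + (a − d) / (1 + (x/c)^b)

with minimum asymptote `a` (AU, the zero-dye response), maximum asymptote
`d` (AU), midpoint `c` (mg/mL) and Hill slope `b`. Conventions:

* **Zero-concentration limit.** `(0/c)^b` is taken as its limit: F(0) = a
  for b > 0 and F(0) = d for b < 0. Negative slopes are accepted
  (decreasing responses) with the asymptote roles swapped.
* **Parameterization symmetry.** The 4PL is exactly invariant under
  (a, b, d) → (d, −b, a). Fits are canonicalized to b > 0, so `a` is always
  the zero-concentration response; a decreasing dataset simply yields
  a > d.
* **Fitting.** Nonlinear least squares on the linear intensity scale over
  all replicate points (Levenberg–Marquardt via trust-region reflective,
  `scipy.optimize.curve_fit`), with multi-start initialization — a at the
  minimum intensity, d at the maximum, c at the geometric mean of the
  concentrations and b ∈ {±0.5, ±1, ±2} — and c bounded positive. The best
  SSR across starts wins; total failure raises a non-convergence error
  carrying the last residual norm.
* **Uncertainty.** `se_regression` = √(SSR/(n−4)). 95% parameter CIs come
  from the asymptotic (Jacobian-based) covariance with Student-t critical
  values at n−4 degrees of freedom. These Wald-type intervals are mildly
  anticonservative at small n: Monte-Carlo checks in the test suite bound
  the midpoint-coverage at ≥90/100 trials under the standard calibration
  protocol (10 concentrations spanning 0.0001–5 mg/mL, 3 replicates,
  σ = 2 AU) rather than asserting the nominal 95%, which a Wald interval
  does not exactly deliver.
* **Inversion.** x = c·((a−d)/(f−d) − 1)^(1/b), defined only for f strictly
  between the asymptotes. Out-of-range intensities raise an error naming
  the violated asymptote; the library never clamps silently — callers (and
  the analysis loop) flag such points instead.
* **Sensitivity region.** The reliable concentration interval is obtained
  by reverse-mapping the 95% CI edge of each asymptote that lies nearest
  the interior of the response (upper edge of `a` and lower edge of `d`
  for an increasing curve). Exactly zero-width CIs put the edges on the
  asymptotes, where the limits are 0 and ∞; this degenerate case raises
  the out-of-range error rather than returning unbounded values.
* **Concentration error.** The regression standard error is reverse-mapped
  symmetrically: err(f) = |x(f+se) − x(f−se)|/2, falling back to a flagged
  one-sided width when only one side is invertible.

## Flat-field (illumination mask) correction

LED illumination is uneven across the field of view. From ≥3 frames at one
uniform dye concentration, the per-pixel multiplier is

    m_ij = mean(P) / P_ij

where P is the pixelwise-mean image. Applying m to P yields a spatially
flat image at the original global mean (the test suite verifies CV < 1e-9),
and re-estimating a mask from corrected frames returns all ones
(idempotence). Note that mean(m) ≥ 1 by Jensen's inequality for any
non-flat field; the normalization convention adopted here preserves the
*global mean intensity* of the corrected calibration image rather than
forcing the multipliers themselves to unit mean — the two conventions
coincide only for a flat field, and the global-mean-preserving form is the
one consistent with the per-pixel ratio definition. One mask is estimated
per LED channel, since the two excitation fields differ.

## Quantification loop

Per acquisition cycle the LEDs fire one at a time in the fixed order cyan
(490 nm) then amber (590 nm); each frame covers both ROIs. The pipeline per
frame: subtract the channel's pre-sample background (clipped at zero — 8-bit
data cannot represent negatives), multiply by the channel's mask, take the
arithmetic mean over each ROI rectangle (0-based, half-open indexing), and
invert the channel's calibration curve. Reported per point:

* capillary/filtrate intensities and concentrations with propagated
  concentration errors;
* **diffusion percentage** 100·C_filtrate/C_capillary,initial, the
  denominator being the first in-range capillary reading of the channel;
* the **instantaneous percentage** relative to the current capillary
  concentration (a separate column, relevant when the capillary load is
  stepped mid-run);
* the filtrate/capillary **intensity ratio** (stability QC; ~1 when both
  channels carry equal loads);
* flags: out-of-range (below/above, concentration omitted, never clamped),
  ROI saturation (>1% of pixels at 255), undefined ratios, missing
  baseline.

## Transport model

The chip is modelled as a lumped-parameter system; all unit conversions are
explicit (`barriersense.units`).

| Quantity | Formula | Units in / out |
|---|---|---|
| Wall shear stress | τ = 6Qµ/(wh²) | cgs → dynes/cm² |
| Hydrostatic pressure | 0.1·(ρgh_cap − ½ρv²) | cgs (barye) → Pa |
| Osmotic pressure | MRT, M = C₀/MW | atm → Pa (×101325) |
| Darcy flux per area | j = (κ/µh_m)·ΔP | µm²·Pa/(Pa·s·µm) = µm/s |
| Volumetric flux | J = j·A·10⁻⁴ | µm/s · cm² → mL/s |
| Steady state | c_f = J·C₀·(V_c/Q)/V_f | mg/mL |
| Transient | c_f(t) = a + b(1 − e^(−t/τ)) | mg/mL |

Notes and choices:

* The volumetric-flux formula multiplies j (µm/s) by the exposed area; the
  dimensionally consistent reading converts A to µm² before the
  10⁻¹² µm³→mL factor, i.e. a net factor of 10⁻⁴ — adopted deliberately and
  tested dimensionally.
* Molarity for the osmotic term uses mg/mL ≡ g/L divided by the tracer's
  molecular weight in g/mol. Whether the free or conjugated MW applies is a
  configuration choice; the defaults are 5000 g/mol for inulin-FITC and
  68000 g/mol for the HSA conjugate.
* Default permeabilities κ = 2.01×10⁻⁴ µm² (inulin-FITC) and
  9.67×10⁻⁴ µm² (HSA–Texas Red) through the 20-µm PCTE membrane; viscosity
  0.006913 poise and density 0.9933 g/cm³ (water, 37 °C); g = 981 cm/s²;
  R = 0.08206 atm·L/(mol·K).
* The three distinct heights (channel height, membrane thickness, capillary
  column height) are separate named fields; likewise the two τ symbols
  (shear stress vs time constant) and the two (a, b) pairs (4PL vs
  transient) live in different types.
* **Permeability estimation** inverts the steady-state chain, which is
  linear in κ. With no explicit perfusion time the membrane exposure time
  V_c/Q is used, making estimation the exact inverse of the forward
  prediction (round-trip tested to 1e-9 relative over three decades of κ);
  a protocol-style estimate passes its measured perfusion duration
  explicitly.
* The filtrate time constant defaults to τ = 120 s and is overridable in
  configuration.
* An impermeable membrane (κ = 0) short-circuits the forward prediction to
  exactly 0 mg/mL, although κ = 0 is rejected by the elementary Darcy
  operation itself.

### Geometry

The chip text fixes only the membrane thickness; absolute channel
dimensions live in configuration, never in code. The packaged default
geometry is **synthetic**: width 0.3 cm and height 0.0866 cm chosen once so
that the shear stress at 100 µL/min is 30.7×10⁻³ dynes/cm² to 3 significant
figures (shear fixes only the product wh²), with plausible values for the
exposed area (0.6 cm²), channel volumes (0.052 / 0.08 mL) and capillary
column height (0.0866 cm). Absolute steady-state predictions therefore
characterize this synthetic chip, not any particular fabricated device;
shear-stress *ratios* across flowrates are geometry-independent.

## Synthetic chip simulator

The simulator composes the same physics the analysis inverts, plus the
camera model:

1. ROI pixels at the 4PL response of their true concentration; the
   non-ROI background at the zero-dye response F(0).
2. Division by the *truth* illumination field (the inverse of the
   correction). The built-in gradient field is normalized to unit mean so
   that mask estimation carries no global gain bias.
3. A uniform dark offset (default 0), optional Poisson shot noise
   (photons/AU scale), Gaussian read noise (default σ = 1 AU), then
   rounding and clipping to [0, 255]. Frames with >50% saturated ROI pixels
   carry a metadata warning.

Experiment dynamics are piecewise first-order: within each protocol
segment the filtrate concentration relaxes from its current value toward
the Darcy steady-state equilibrium of that segment's (C₀, Q) with time
constant τ; segment boundaries are instantaneous step inputs (injections
are treated as steps) and the boundary value carries over exactly, so the
trace is continuous. The commanded capillary concentration is the ground
truth (reservoir dilution is out of scope). Everything is deterministic
under a fixed seed.

What the simulator does **not** emulate — hence what passing tests do not
establish about real data: optical point-spread and defocus, spectral
crosstalk between dyes, photobleaching, temporal illumination drift, flow
pulsatility, bubbles/debris, and any cellular-layer resistance. Tests
validate the *pipeline's* correctness and error propagation, not the
optical fidelity of a physical instrument.

### Test problem sizes

Image-based tests render 120×160-pixel frames (the full 507×380 sensor
resolution changes nothing in the per-pixel arithmetic); Monte-Carlo checks
use 100 seeded trials; the end-to-end experiment is the three-step gradient
protocol (0.1 → 0.2 → 0.4 mg/mL at 8 µL/min, 15 s sampling, 121 cycles)
with calibration from 12 concentrations × 10 replicates at σ = 2 AU. The
densely replicated calibration is deliberate: the propagated concentration
error describes single-reading regression noise, so the curve's own bias
must be kept small relative to it for the bound to be meaningful.

## Known limitations

* The steady-state model is monotone and super-linear in C₀ (the osmotic
  term grows with C₀); it cannot produce a non-monotone diffusion fraction
  across capillary loads.
* Wald CIs slightly undercover at small calibration sizes (see above);
  profile-likelihood intervals would be more accurate but are not
  implemented.
* The acquisition scheduler models event ordering and timing only; it does
  not model exposure duration within the ~7 s minimum cycle time.
* Replicate-trace alignment at injection points is not implemented; traces
  are aligned by their protocol timestamps.
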