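# Methods

## Constitutive models and stress correction

The package analyzes micropipette-aspiration creep: a single step in suction
pressure, held constant while the aspirated length `L_p(t)` is imaged.
Strain is defined as `ε = (L_p − L_0)/R_p`, normalized so the first retained
frame has `ε = 0`. The material family is restricted to one-dimensional
spring-dashpot models with at most two elements, whose common creep response
is `ε(t) = A + B·t + C·e^(−D·t)`:

| model | constraint | response | parameters |
|---|---|---|---|
| Newtonian | A=C=0 | `σt/η` | `η = σ/B` |
| Maxwell | C=0 | `σ/E + σt/η` | `E = σ/A`, `η = σ/B` |
| Kelvin-Voigt | B=0, A=−C, D>0 | `(σ/E)(1 − e^(−(E/η)t))` | `E = σ/A`, `η = E/D` |

A pure spring is deliberately absent: no aspiration curve plateaus
instantaneously. Three-or-more-element models are out of scope — extra
elements always reduce residuals but add no interpretable insight at these
data densities.

The Maxwell model's instantaneous elastic jump `σ/E` conflicts with the
`ε(0) = 0` normalization; `strain_response` returns 0 at exactly `t = 0`
and the jump is exposed separately (`maxwell_jump`), with the fitted `A`
absorbing it. Maxwell is retained only as a comparator: on solid-like data
it returns implausible moduli, which is itself a diagnostic.

The stress in all conversions is the Laplace-corrected effective stress
`σ = P − Σ 2γ(1/R_p − 1/R_c)` over every listed interface. Negative `σ` is
allowed and flagged (capillarity-driven retraction), not an error. A
dimensionless `geometric_prefactor` (default 1) multiplies `σ` before
parameter conversion: the one-dimensional effective viscosity differs from
the true shear viscosity by a flow-geometry factor that the package does not
attempt to compute.

Units are fixed everywhere: Pa, µm, s, µN/m, Pa·s. These make
`2γ/R_p` come out in Pa and `η/γ` in s/µm with no conversion constants,
verified by a unit self-test.

## Fitting and model selection

Fits use constrained nonlinear least squares (`scipy.optimize.curve_fit`)
with a deterministic initialization: `B₀` = end-to-end secant slope; for
Kelvin-Voigt `A₀` = final strain and `D₀ = ln 2 / t_half` where `t_half` is
the time to half the final strain. On failure the optimizer restarts from a
fixed multiplicative perturbation schedule (×0.5, ×2, ×0.1, ×10, ×1.5) — no
randomness, so identical inputs give identical fits. `D` is bounded to
(1e-5, 10) s⁻¹: frame intervals of 1–2 s and experiment durations of minutes
bracket the resolvable decay rates. Non-convergence is flagged on the fit
object, never silent.

Model selection is parsimony-adjusted: a two-parameter model (Maxwell or
Kelvin-Voigt) displaces the Newtonian fit only if it reduces the mean squared
error by at least a configurable factor (default 2). The factor-2 default is
deliberately lenient relative to the MSE contrasts seen on genuinely
solid-like data (well above 6×) while still refusing one-parameter-worth
improvements; all candidate fits are returned for audit. At zero noise a
richer model can never displace the true simpler one, since both then fit
exactly.

Cohort aggregation averages coefficients within each nucleolus first, then
converts to material parameters with that nucleolus's mean effective stress,
then averages across nucleoli — so a nucleolus measured five times counts
once. Reported uncertainty is the SEM over nucleolus-level values
(biological scatter dominates measurement error at these scales); a
propagation-of-error alternative, combining per-nucleolus standard errors in
quadrature, is reported alongside. SEM over a single nucleolus is NaN, not
zero.

## Interfacial tension inference

For a Newtonian phase `B = (P − P_γ)/η`, so `B` regressed on `P` crosses
zero at `P = P_γ`. The fit is weighted least squares with weights `1/se_B²`
(the standard inverse-variance rule; `1/se_B` is available via config), and
the reported intercept is the **pressure-axis** intercept `P₀ = −b/m` — the
only intercept with units of pressure, and exactly the pressure at which
flow stops. Its uncertainty comes from first-order propagation through the
(slope, intercept) covariance. Division by the curvature term
`2(1/R_p − 1/R_c)`, using each sample's own radii, gives `γ`; samples are
averaged unweighted. Whether to regress B on P or P on B is genuinely open
(the two intercepts differ under noise); B-on-P is fixed here because `se_B`
is the stated noise channel.

For composite interfaces (an outer droplet surface plus an internal
subcompartment boundary) the apparent tension decomposes additively; the
inner tension is the difference, with errors combined in quadrature. A
negative difference is returned flagged, never clipped — it means the
assumed outer tension is inconsistent with the measurement.

## Kymograph front tracking

Rows are frames, column 0 is the pipette tip, pixel `i` covers `[i, i+1)`.
Segmentation thresholds the whole kymograph at once (Otsu by default;
per-kymograph rather than per-frame to avoid threshold jitter; a
fixed-fraction mode exists). The front is the far edge of the above-threshold
run attached to the tip, refined to sub-pixel precision by interpolating the
intensity profile at the half-height between the plateau median and the
background median — this makes an ideal integer-position step exact and
keeps partial-pixel fronts within ~0.1 px. Frames with nothing above
threshold at the tip record front 0 with an `empty` flag; fully saturated
frames record the grid extent with a `saturated` flag.

Necking (pinch-off of the aspirated column into detached slugs) is detected
as a split of the above-threshold region into runs separated by a gap of at
least 2 px (configurable) persisting for at least 2 consecutive frames;
single-frame flicker does not qualify. Flagged traces are carried through
extraction but excluded from creep fitting. The pipette radius is always an
input (measured from transmitted-light images in practice), never estimated
from fluorescence.

## Fusion analysis

Coalescing droplets relax as `AR(t) = 1 + (AR₀ − 1)e^(−t/τ)`; t = 0 is the
first frame at which the fused object is a single connected region. `AR₀` is
constrained ≥ 1; events whose excursion above 1 never exceeds a noise floor
(default 1e-3) are flagged degenerate with τ undefined. The size scaling
`τ = (η/γ)·l`, with `l` the geometric mean of the initial axes, has no
intercept, so the primary τ-vs-l fit is constrained through the origin
(slope `Στl/Σl²`); a free-intercept diagnostic fit is reported alongside.
Events are unweighted — per-event τ uncertainties are typically comparable,
and the unweighted slope is the simplest defensible estimator.

## Synthetic data

The generators produce every input with known ground truth, at the
measurement conditions the analysis is designed for: creep traces sampled at
2 s/frame for 300 s at 5–40 Pa; multi-pressure Newtonian series sharing one
Laplace offset; kymographs rendered as step profiles with partial-pixel
front coverage and optional carved necking gaps; fusion events at 30 s/frame
(4 s for fast-relaxing treated material, where the generator warns if
`τ < 2` frames — undersampled relaxations fit unreliably). Phase presets
carry the measured magnitudes: GC Newtonian η = 220 Pa·s; DFC Kelvin-Voigt
η = 250 Pa·s, E = 3.1 Pa; RNase-fluidized DFC Newtonian η = 1000 Pa·s;
tensions 1.7 (GC–nucleoplasm), 0.5 (GC–DFC bound), 8.0 µN/m (treated
composite).

Noise is additive Gaussian on the observables (Lp, AR, B) — the simplest
model consistent with pixel-level measurement error — with sd expressed
against a natural scale (plateau strain, step height, true B). Default Lp
noise is pixel-scale (~0.02–0.05 µm). Optional cohort dispersion is a
lognormal multiplier on η (σ = 1.15 spans roughly two orders of magnitude
across ~20 nucleoli, matching the observed biological spread). Necking is
injected as a geometric gap, not simulated hydrodynamically. Every
stochastic generator requires an explicit seed and is bit-reproducible.

What the generators do **not** emulate: drift and registration artifacts,
shot noise and denoising residues, wetting films, the GC plug's modification
of the effective pressure on the DFC, time-since-isolation viscosity drift,
and spatial heterogeneity within a phase. Passing recovery tests therefore
demonstrates correctness of the inference chain under the stated noise
model, not robustness to every artifact of real microscopy.

## Problem sizes and tolerances

Recovery runs use 20 traces/series/events per condition (30 for the τ–l
slope, 100 for model-selection rates), sizes at which medians are stable
across seeds while the whole suite completes in well under a minute per
stage. Noiseless round trips are asserted at machine-level tolerances
(strain 1e-12 relative, coefficients 1e-6, Laplace/tension inversion 1e-12);
noisy recoveries at 5–15% depending on the stage's leverage (tension, which
extrapolates to an intercept, is the loosest). Ejection/relaxation segments
after pressure release are generated for realism but never fitted; the
aspiration segment alone determines solid- versus liquid-like behavior.

## Known limitations

Effective parameters are one-dimensional: mapping to true shear moduli
requires the three-dimensional flow problem, exposed only as the
`geometric_prefactor`. The Otsu default is a choice where the original
segmentation rule is unspecified. Per-nucleolus averaging operates on
coefficients (then converts with the mean stress context); if traces of one
nucleolus had very different Laplace contexts, averaging converted
parameters instead could differ — the coefficient route is fixed here.
Frequency-domain (cyclic) viscoelasticity and three-element models are out
of scope.
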