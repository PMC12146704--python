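# nucleorheo

Micropipette-aspiration (MPA) rheology of multiphase biomolecular
condensates, built around the nucleolus of the *Xenopus laevis* oocyte
nucleus. The nucleolus is a layered droplet: an outer granular component
(GC) that flows like a Newtonian liquid, and an inner dense fibrillar
component (DFC) that behaves like an RNA-dependent viscoelastic solid.
`nucleorheo` turns raw MPA observations — fluorescence kymographs of the
aspirated column, aspirated-length time series, droplet-fusion aspect-ratio
series — into effective viscosities, elastic moduli, and interfacial
tensions with uncertainties.

## The model

A creep test applies a constant suction pressure `P` through a pipette of
radius `R_p` and records the aspirated length `L_p(t)`. Strain is
`ε = (L_p − L_0)/R_p`. The stress actually driving the material is the
applied pressure minus the Laplace pressure of every curved interface,

    σ = P − Σ 2γ (1/R_p − 1/R_c),

with `γ` the interfacial tension and `R_c` the radius of the droplet outside
the pipette. Every one-dimensional spring-dashpot model with up to two
elements responds to constant stress as

    ε(t) = A + B·t + C·e^(−D·t)

with per-model constraints: Newtonian (`A=C=0`), Maxwell (`C=0`),
Kelvin-Voigt (`B=0`, `A=−C`). The fitted coefficients convert to material
parameters (`η = σ/B` for fluids; `E = σ/A`, `η = E/D` for the Kelvin-Voigt
solid). Tension is inferred independently from how the Newtonian flow
coefficient `B = (P − P_γ)/η` varies with pressure: the pressure-axis
intercept of a weighted linear fit is the Laplace pressure, hence `γ`.
Coalescing droplets give a third, orthogonal probe: the aspect ratio relaxes
as `AR = 1 + (AR₀−1)e^(−t/τ)` with `τ = (η/γ)·l`, so the slope of `τ`
against droplet size `l` is the inverse capillary velocity `η/γ` (s/µm).

Units are fixed package-wide — Pa, µm, s, µN/m, Pa·s — so that
`2γ/R_p` is in Pa and `η/γ` is in s/µm with no conversion factors.

## Worked example

```python
import numpy as np
from nucleorheo import (
    Interface, MaterialParams, ModelClass, StressContext,
    compute_strain, fit_model, coefficients_to_params,
    inverse_capillary_velocity,
)
from nucleorheo import synthetic as syn

# A DFC-like Kelvin-Voigt solid aspirated at 20 Pa through a 1 um pipette,
# with the 1.7 uN/m outer-interface Laplace correction (3.4 Pa).
ctx = StressContext(20.0, (Interface(gamma=1.7, Rp=1.0),))
truth = MaterialParams(eta_eff=250.0, E_eff=3.1)
trace = syn.simulate_aspiration_trace(
    ModelClass.KELVIN_VOIGT, truth, ctx,
    duration=300.0, frame_interval=2.0, noise_sd=0.05, seed=1,
)
fit = fit_model(compute_strain(trace), trace.times, ModelClass.KELVIN_VOIGT)
params = coefficients_to_params(
    ModelClass.KELVIN_VOIGT, A=fit.A, D=fit.D, sigma=ctx.effective_stress,
    se_A=fit.se["A"], se_D=fit.se["D"],
)
print(f"sigma_eff = {ctx.effective_stress:.2f} Pa")
print(f"eta = {params.eta_eff:.1f} +/- {params.eta_err:.1f} Pa.s")
print(f"E   = {params.E_eff:.2f} +/- {params.E_err:.2f} Pa")
print(f"eta/gamma = {inverse_capillary_velocity(params.eta_eff, 1.7):.0f} s/um")
```

prints

```
sigma_eff = 16.60 Pa
eta = 250.4 +/- 1.3 Pa.s
E   = 3.10 +/- 0.01 Pa
eta/gamma = 147 s/um
```

The effective stress is 20 Pa minus the 3.4 Pa Laplace pressure; the fit
recovers the generating viscosity and modulus within the noise-limited
uncertainty of a single trace.

A CLI wraps the pipeline (`nucleorheo simulate|extract|fit|tension|fusion|report`):

```sh
nucleorheo --seed 4 simulate --phase GC --pressure 5 --out traces.csv
nucleorheo fit traces.csv --gamma 1.7 --out fit.json
```

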