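"""Fit aspiration creep traces to the two-element model family.

A trace is the aspirated length Lp(t) at constant suction pressure.  Strain
is eps = (Lp - L0)/Rp with L0 the aspirated length at aspiration onset, so
eps(first retained frame) = 0 by construction.  Each trace is fitted under
each model-class constraint (see `nucleorheo.models`), a winner is chosen by
a parsimony-adjusted mean-squared-error rule, and coefficients are averaged
within each nucleolus before conversion to material parameters, so nucleoli
measured more often do not dominate the cohort mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .models import (
    MaterialParams,
    ModelClass,
    StressContext,
    coefficients_to_params,
)

__all__ = [
    "AspirationTrace",
    "ModelFit",
    "CohortEstimate",
    "compute_strain",
    "fit_model",
    "select_model",
    "aggregate_params",
]

# Resolvable rate window: frames arrive every 1-2 s and experiments last
# minutes, so decay rates outside (1e-5, 10) 1/s cannot be constrained.
D_BOUNDS = (1e-5, 10.0)


@dataclass
class AspirationTrace:
    """One constant-pressure aspiration segment.

    times in s (strictly increasing), Lp in um, pressure in Pa, radii in um.
    ``phase`` is a free label (e.g. GC, DFC, DFC_RNase).  ``necking_flag``
    marks traces where the aspirated column fragmented; they are excluded
    from fitting.
    """

    times: np.ndarray
    Lp: np.ndarray
    P: float
    Rp: float
    Rc: float = math.inf
    phase: str = "GC"
    trace_id: str = "trace"
    nucleolus_id: str = "nucleolus"
    L0: Optional[float] = None
    necking_flag: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.Lp = np.asarray(self.Lp, dtype=float)
        if self.times.shape != self.Lp.shape:
            raise ValueError("times and Lp must have equal length")
        if len(self.times) < 5:
            raise ValueError(f"trace needs >= 5 points, got {len(self.times)}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"trace {self.trace_id!r}: times must be strictly increasing")
        if np.any(self.Lp < 0):
            raise ValueError("aspirated lengths must be >= 0")
        if self.Rp <= 0:
            raise ValueError(f"pipette radius must be > 0, got {self.Rp}")
        if self.L0 is None:
            self.L0 = float(self.Lp[0])


@dataclass
class ModelFit:
    """Coefficients of one constrained creep fit with diagnostics.

    A, C dimensionless; B, D in 1/s.  ``se`` maps each free coefficient to
    its standard error.  ``mse`` is the mean squared strain residual.
    """

    model: ModelClass
    A: float
    B: float
    C: float
    D: float
    se: Dict[str, float]
    mse: float
    converged: bool
    n_points: int
    trace_id: str = ""
    nucleolus_id: str = ""

    @property
    def coefficients(self) -> Dict[str, float]:
        return {"A": self.A, "B": self.B, "C": self.C, "D": self.D}


@dataclass
class CohortEstimate:
    """Cohort-level material parameter with per-nucleolus provenance.

    ``sem`` is computed over nucleolus-level values (NaN for a single
    nucleolus); ``propagated_uncertainty`` combines the per-nucleolus
    standard errors in quadrature as an alternative error estimate.
    """

    parameter: str
    per_nucleolus: Dict[str, float]
    mean: float
    sem: float
    propagated_uncertainty: Optional[float]
    n_nucleoli: int
    n_measurements: int


def compute_strain(trace: AspirationTrace) -> np.ndarray:
    """Dimensionless strain eps_i = (Lp_i - L0)/Rp; exactly 0 at the first frame."""
    return (trace.Lp - trace.L0) / trace.Rp


def _initial_guess(model: ModelClass, t: np.ndarray, eps: np.ndarray) -> List[float]:
    # Deterministic, scale-aware initialization: B0 from the end-to-end
    # secant slope; for Kelvin-Voigt A0 = final strain and D0 = ln2 over the
    # time to reach half of the final strain.
    total_t = t[-1] - t[0] if t[-1] > t[0] else 1.0
    final = eps[-1]
    b0 = max(final / total_t, 1e-8)
    if model is ModelClass.NEWTONIAN:
        return [b0]
    if model is ModelClass.MAXWELL:
        return [max(final * 0.1, 1e-8), b0]
    a0 = max(final, 1e-8)
    half = 0.5 * final
    above = np.nonzero(eps >= half)[0]
    t_half = t[above[0]] - t[0] if len(above) and t[above[0]] > t[0] else total_t / 2
    d0 = float(np.clip(math.log(2.0) / t_half, *D_BOUNDS))
    return [a0, d0]


def _model_fn(model: ModelClass):
    if model is ModelClass.NEWTONIAN:
        return lambda t, B: B * t
    if model is ModelClass.MAXWELL:
        # eps(0)=0 normalization: the fitted A absorbs the instantaneous jump
        # but the first frame is pinned at zero strain by construction.
        return lambda t, A, B: np.where(t > 0, A + B * t, 0.0)
    return lambda t, A, D: A * (1.0 - np.exp(-D * t))


def _bounds(model: ModelClass) -> Tuple[list, list]:
    if model is ModelClass.NEWTONIAN:
        return ([0.0], [np.inf])
    if model is ModelClass.MAXWELL:
        return ([0.0, 0.0], [np.inf, np.inf])
    return ([0.0, D_BOUNDS[0]], [np.inf, D_BOUNDS[1]])


def fit_model(
    strain: Sequence[float],
    times: Sequence[float],
    model: ModelClass,
    *,
    trace_id: str = "",
    nucleolus_id: str = "",
    max_restarts: int = 5,
) -> ModelFit:
    """Constrained nonlinear least squares of the creep law on one trace.

    Deterministic: a fixed initialization rule plus, on failure, up to
    ``max_restarts`` restarts from a fixed multiplicative perturbation
    schedule (no randomness).  Non-convergence is flagged, never silent.
    """
    t = np.asarray(times, dtype=float)
    eps = np.asarray(strain, dtype=float)
    if len(t) < 5:
        raise ValueError("need >= 5 points to fit")
    t = t - t[0]  # aspiration clock starts at the first retained frame

    fn = _model_fn(model)
    lo, hi = _bounds(model)
    p0 = _initial_guess(model, t, eps)
    names = model.free_coefficients

    best = None
    # Fixed perturbation schedule: scale all initials by these factors in turn.
    for factor in [1.0, 0.5, 2.0, 0.1, 10.0, 1.5][: max_restarts + 1]:
        start = [min(max(p * factor, l + 1e-12), h if np.isfinite(h) else p * factor)
                 for p, l, h in zip(p0, lo, hi)]
        try:
            popt, pcov = curve_fit(
                fn, t, eps, p0=start, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = eps - fn(t, *popt)
        mse = float(np.mean(resid**2))
        if best is None or mse < best[2] * (1 - 1e-10):
            best = (popt, pcov, mse)
            if mse < 1e-20:
                break

    if best is None:
        return ModelFit(
            model=model, A=0.0, B=0.0, C=0.0, D=0.0, se={}, mse=math.inf,
            converged=False, n_points=len(t),
            trace_id=trace_id, nucleolus_id=nucleolus_id,
        )

    popt, pcov, mse = best
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    se = {n: float(e) for n, e in zip(names, perr)}
    coef = dict(zip(names, (float(v) for v in popt)))
    A = coef.get("A", 0.0)
    B = coef.get("B", 0.0)
    D = coef.get("D", 0.0)
    C = -A if model is ModelClass.KELVIN_VOIGT else 0.0
    return ModelFit(
        model=model, A=A, B=B, C=C, D=D, se=se, mse=mse, converged=True,
        n_points=len(t), trace_id=trace_id, nucleolus_id=nucleolus_id,
    )


def select_model(
    strain: Sequence[float],
    times: Sequence[float],
    *,
    mse_ratio_threshold: float = 2.0,
    trace_id: str = "",
    nucleolus_id: str = "",
) -> Tuple[ModelClass, Dict[ModelClass, ModelFit]]:
    """Fit all candidate models and pick a parsimony-adjusted winner.

    A two-parameter model (Maxwell or Kelvin-Voigt) displaces the
    one-parameter Newtonian fit only if it reduces the mean squared error by
    at least ``mse_ratio_threshold``; among equally complex models the lower
    MSE wins.  All candidate fits are returned for audit.
    """
    fits = {
        m: fit_model(strain, times, m, trace_id=trace_id, nucleolus_id=nucleolus_id)
        for m in ModelClass
    }
    converged = {m: f for m, f in fits.items() if f.converged}
    if not converged:
        raise RuntimeError("no candidate model converged")

    simple = converged.get(ModelClass.NEWTONIAN)
    richer = [converged[m] for m in (ModelClass.MAXWELL, ModelClass.KELVIN_VOIGT)
              if m in converged]
    richer.sort(key=lambda f: f.mse)

    if simple is None:
        return richer[0].model, fits
    if not richer:
        return ModelClass.NEWTONIAN, fits
    best_rich = richer[0]
    if best_rich.mse == 0.0:
        wins = simple.mse > 0.0
    else:
        wins = simple.mse / best_rich.mse >= mse_ratio_threshold
    return (best_rich.model if wins else ModelClass.NEWTONIAN), fits


def aggregate_params(
    fits: Sequence[ModelFit],
    contexts: Mapping[str, StressContext] | Sequence[StressContext],
    *,
    model: Optional[ModelClass] = None,
    geometric_prefactor: float = 1.0,
) -> Dict[str, CohortEstimate]:
    """Cohort material parameters with within-nucleolus averaging first.

    Coefficients are averaged within each nucleolus (so a nucleolus measured
    many times counts once), converted to material parameters with that
    nucleolus's mean effective stress, then averaged across nucleoli with the
    SEM over nucleolus-level values.  ``contexts`` maps nucleolus_id (or, as a
    sequence, parallels ``fits``) to the stress context.

    Returns estimates keyed by parameter name ("eta_eff", and "E_eff" for
    viscoelastic models).
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to aggregate")
    if model is None:
        model = fits[0].model
    if any(f.model is not model for f in fits):
        raise ValueError("all fits must share one model class to aggregate")

    if not isinstance(contexts, Mapping):
        if len(contexts) != len(fits):
            raise ValueError("one stress context per fit required")
        ctx_of: Dict[str, List[StressContext]] = {}
        for f, c in zip(fits, contexts):
            ctx_of.setdefault(f.nucleolus_id, []).append(c)
    else:
        ctx_of = {f.nucleolus_id: [contexts[f.nucleolus_id]] for f in fits}

    groups: Dict[str, List[ModelFit]] = {}
    for f in fits:
        groups.setdefault(f.nucleolus_id, []).append(f)

    per_nuc_params: Dict[str, MaterialParams] = {}
    for nid, group in groups.items():
        mean_coef = {
            k: float(np.mean([f.coefficients[k] for f in group]))
            for k in ("A", "B", "C", "D")
        }
        # SE of the within-nucleolus mean coefficient, from per-fit SEs
        mean_se = {
            k: math.sqrt(sum(f.se.get(k, 0.0) ** 2 for f in group)) / len(group)
            for k in ("A", "B", "D")
        }
        sigma = float(np.mean([c.effective_stress for c in ctx_of[nid]]))
        per_nuc_params[nid] = coefficients_to_params(
            model,
            **mean_coef,
            sigma=sigma,
            se_A=mean_se["A"],
            se_B=mean_se["B"],
            se_D=mean_se["D"],
            geometric_prefactor=geometric_prefactor,
        )

    out: Dict[str, CohortEstimate] = {}
    specs = [("eta_eff", lambda p: p.eta_eff, lambda p: p.eta_err)]
    if model is not ModelClass.NEWTONIAN:
        specs.append(("E_eff", lambda p: p.E_eff, lambda p: p.E_err))
    n_meas = len(fits)
    for name, value_of, err_of in specs:
        vals = {nid: value_of(p) for nid, p in per_nuc_params.items()}
        arr = np.array(list(vals.values()), dtype=float)
        sem = float(np.std(arr, ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else math.nan
        errs = [err_of(p) for p in per_nuc_params.values()]
        prop = (
            math.sqrt(sum(e**2 for e in errs)) / len(errs)
            if all(e is not None for e in errs)
            else None
        )
        out[name] = CohortEstimate(
            parameter=name,
            per_nucleolus=vals,
            mean=float(arr.mean()),
            sem=sem,
            propagated_uncertainty=prop,
            n_nucleoli=len(arr),
            n_measurements=n_meas,
        )
    return out
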