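"""Constitutive model family and stress relations for micropipette aspiration.

The creep response of a droplet aspirated at constant suction pressure is
described, for all one-dimensional spring-dashpot models with up to two
elements, by

    eps(t) = A + B*t + C*exp(-D*t)

with a per-model constraint set:

* ``newtonian``     (dashpot):            A = C = 0, B free
* ``maxwell``       (spring + dashpot in series): C = 0, A and B free
* ``kelvin_voigt``  (spring + dashpot in parallel): B = 0, A = -C, A and D free

The effective stress driving the creep is the applied pressure corrected for
the Laplace pressure of every curved interface inside/outside the pipette:
``sigma = P - sum(2*gamma*(1/Rp - 1/Rc))``.

Unit convention, fixed package-wide: pressure in Pa, length in um, time in s,
interfacial tension in uN/m, viscosity in Pa*s.  These are chosen so that
``2*gamma/Rp`` is in Pa and ``eta/gamma`` is in s/um with no conversion
factors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ModelClass",
    "Interface",
    "StressContext",
    "MaterialParams",
    "laplace_pressure",
    "effective_stress",
    "strain_response",
    "maxwell_jump",
    "coefficients_to_params",
    "params_to_coefficients",
    "inverse_capillary_velocity",
]


class ModelClass(enum.Enum):
    """Two-element spring-dashpot model classes.

    A pure Hookean (spring-only) class is deliberately absent: aspirated
    condensates always show time-dependent creep, never an instantaneous
    plateau.
    """

    NEWTONIAN = "newtonian"
    MAXWELL = "maxwell"
    KELVIN_VOIGT = "kelvin_voigt"

    @property
    def free_coefficients(self) -> Tuple[str, ...]:
        return {
            ModelClass.NEWTONIAN: ("B",),
            ModelClass.MAXWELL: ("A", "B"),
            ModelClass.KELVIN_VOIGT: ("A", "D"),
        }[self]

    @property
    def n_free(self) -> int:
        return len(self.free_coefficients)

    @classmethod
    def from_name(cls, name: str) -> "ModelClass":
        try:
            return cls(name.lower())
        except ValueError:
            raise ValueError(
                f"unknown model class {name!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


class InvalidGeometryError(ValueError):
    """Pipette/droplet geometry violates Rc >= Rp > 0."""


class UnphysicalFitError(ValueError):
    """Fit coefficients imply nonpositive viscosity or modulus."""


def laplace_pressure(gamma: float, Rp: float, Rc: float = math.inf) -> float:
    """Laplace pressure drop across the aspirated interface, in Pa.

    P_gamma = 2*gamma*(1/Rp - 1/Rc), where ``Rp`` is the pipette opening
    radius and ``Rc`` the radius of the droplet portion outside the pipette.
    ``Rc = inf`` models an effectively flat outer interface.  With gamma in
    uN/m and radii in um the result is in Pa directly.
    """
    if gamma < 0:
        raise ValueError(f"interfacial tension must be >= 0, got {gamma}")
    if Rp <= 0:
        raise InvalidGeometryError(f"pipette radius must be > 0, got {Rp}")
    if not math.isinf(Rc) and Rc < Rp:
        raise InvalidGeometryError(
            f"outer droplet radius Rc={Rc} smaller than pipette radius Rp={Rp}"
        )
    inv_rc = 0.0 if math.isinf(Rc) else 1.0 / Rc
    return 2.0 * gamma * (1.0 / Rp - inv_rc)


@dataclass(frozen=True)
class Interface:
    """One curved interface contributing a Laplace term.

    gamma in uN/m, radii in um; ``Rc = inf`` for a flat outer surface.
    """

    gamma: float
    Rp: float
    Rc: float = math.inf

    def __post_init__(self) -> None:
        laplace_pressure(self.gamma, self.Rp, self.Rc)  # validates

    @property
    def pressure(self) -> float:
        return laplace_pressure(self.gamma, self.Rp, self.Rc)


@dataclass(frozen=True)
class StressContext:
    """Applied pressure plus the Laplace terms acting on the aspirated phase.

    ``geometric_prefactor`` (default 1) multiplies the effective stress before
    any conversion to material parameters; it stands in for the dimensionless
    factor relating the one-dimensional effective viscosity to the true shear
    viscosity, which depends on the full flow geometry and is not computed
    here.
    """

    applied_pressure: float
    interfaces: Tuple[Interface, ...] = ()
    geometric_prefactor: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.applied_pressure):
            raise ValueError("applied pressure must be finite")
        object.__setattr__(self, "interfaces", tuple(self.interfaces))

    @property
    def laplace_total(self) -> float:
        return sum(i.pressure for i in self.interfaces)

    @property
    def effective_stress(self) -> float:
        return self.applied_pressure - self.laplace_total

    @property
    def capillarity_dominates(self) -> bool:
        """True when the Laplace terms exceed the applied pressure (retraction)."""
        return self.effective_stress < 0


def effective_stress(ctx: StressContext) -> float:
    """sigma = P - sum of Laplace pressures; may be negative (retraction)."""
    return ctx.effective_stress


@dataclass(frozen=True)
class MaterialParams:
    """Material parameters of one aspirated phase.

    eta_eff : effective viscosity, Pa*s
    E_eff   : effective elastic modulus, Pa (None for a Newtonian fluid)
    gamma   : relevant interfacial tension, uN/m (optional)
    *_err   : one-sigma uncertainties, same units
    """

    eta_eff: float
    E_eff: Optional[float] = None
    gamma: Optional[float] = None
    eta_err: Optional[float] = None
    E_err: Optional[float] = None
    gamma_err: Optional[float] = None
    model: Optional[ModelClass] = None
    stress: Optional[StressContext] = None

    def __post_init__(self) -> None:
        if not (self.eta_eff > 0):
            raise UnphysicalFitError(f"eta_eff must be > 0, got {self.eta_eff}")
        if self.E_eff is not None and not (self.E_eff > 0):
            raise UnphysicalFitError(f"E_eff must be > 0, got {self.E_eff}")


def strain_response(
    model: ModelClass,
    params: MaterialParams,
    sigma: float,
    t,
):
    """Forward creep strain at constant stress, normalized to eps(0) = 0.

    newtonian    : sigma*t/eta
    maxwell      : sigma/E + sigma*t/eta for t > 0 (0 at t = 0; the
                   instantaneous elastic jump is reported by `maxwell_jump`)
    kelvin_voigt : (sigma/E) * (1 - exp(-(E/eta) t))

    ``t`` may be a scalar or array of times in s; returns matching shape.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    eta = params.eta_eff
    if model is ModelClass.NEWTONIAN:
        out = sigma * t / eta
    elif model is ModelClass.MAXWELL:
        if params.E_eff is None:
            raise UnphysicalFitError("maxwell model requires an elastic modulus")
        out = np.where(t > 0, sigma / params.E_eff + sigma * t / eta, 0.0)
    elif model is ModelClass.KELVIN_VOIGT:
        if params.E_eff is None:
            raise UnphysicalFitError("kelvin_voigt model requires an elastic modulus")
        E = params.E_eff
        out = (sigma / E) * (1.0 - np.exp(-(E / eta) * t))
    else:  # pragma: no cover
        raise ValueError(f"unknown model {model}")
    return out.item() if out.ndim == 0 else out


def maxwell_jump(params: MaterialParams, sigma: float) -> float:
    """Instantaneous elastic strain jump sigma/E of the Maxwell model (t -> 0+)."""
    if params.E_eff is None:
        raise UnphysicalFitError("maxwell jump requires an elastic modulus")
    return sigma / params.E_eff


def coefficients_to_params(
    model: ModelClass,
    A: float = 0.0,
    B: float = 0.0,
    C: float = 0.0,
    D: float = 0.0,
    *,
    sigma: float,
    se_A: float = 0.0,
    se_B: float = 0.0,
    se_D: float = 0.0,
    geometric_prefactor: float = 1.0,
    stress: Optional[StressContext] = None,
) -> MaterialParams:
    """Convert fitted creep coefficients into material parameters.

    newtonian    : eta = sigma/B
    maxwell      : E = sigma/A, eta = sigma/B
    kelvin_voigt : E = sigma/A, eta = sigma/(A*D) = E/D

    ``sigma`` is the effective stress (Pa); ``geometric_prefactor`` rescales it
    before conversion.  Uncertainties are first-order propagated from the
    coefficient standard errors (coefficients treated as uncorrelated).
    """
    if sigma <= 0:
        raise ValueError(f"effective stress must be > 0 to invert, got {sigma}")
    s = sigma * geometric_prefactor
    if model is ModelClass.NEWTONIAN:
        if B <= 0:
            raise UnphysicalFitError(f"newtonian fit requires B > 0, got {B}")
        eta = s / B
        eta_err = eta * (se_B / B) if se_B else None
        return MaterialParams(eta_eff=eta, eta_err=eta_err, model=model, stress=stress)
    if model is ModelClass.MAXWELL:
        if B <= 0 or A <= 0:
            raise UnphysicalFitError(
                f"maxwell fit requires A > 0 and B > 0, got A={A}, B={B}"
            )
        eta = s / B
        E = s / A
        return MaterialParams(
            eta_eff=eta,
            E_eff=E,
            eta_err=eta * (se_B / B) if se_B else None,
            E_err=E * (se_A / A) if se_A else None,
            model=model,
            stress=stress,
        )
    if model is ModelClass.KELVIN_VOIGT:
        if A <= 0 or D <= 0:
            raise UnphysicalFitError(
                f"kelvin_voigt fit requires A > 0 and D > 0, got A={A}, D={D}"
            )
        if C and not math.isclose(C, -A, rel_tol=1e-9, abs_tol=1e-12):
            raise UnphysicalFitError(
                f"kelvin_voigt requires C = -A (eps(0)=0), got A={A}, C={C}"
            )
        E = s / A
        eta = s / (A * D)
        rel_A = se_A / A if se_A else 0.0
        rel_D = se_D / D if se_D else 0.0
        eta_err = eta * math.hypot(rel_A, rel_D) if (se_A or se_D) else None
        return MaterialParams(
            eta_eff=eta,
            E_eff=E,
            eta_err=eta_err,
            E_err=E * rel_A if se_A else None,
            model=model,
            stress=stress,
        )
    raise ValueError(f"unknown model {model}")  # pragma: no cover


def params_to_coefficients(
    model: ModelClass, params: MaterialParams, sigma: float
) -> dict:
    """Forward map: material parameters -> creep coefficients (A, B, C, D).

    Exact inverse of `coefficients_to_params` on valid parameter sets.
    """
    if sigma <= 0:
        raise ValueError(f"effective stress must be > 0, got {sigma}")
    eta = params.eta_eff
    if model is ModelClass.NEWTONIAN:
        return {"A": 0.0, "B": sigma / eta, "C": 0.0, "D": 0.0}
    if model is ModelClass.MAXWELL:
        return {"A": sigma / params.E_eff, "B": sigma / eta, "C": 0.0, "D": 0.0}
    if model is ModelClass.KELVIN_VOIGT:
        A = sigma / params.E_eff
        return {"A": A, "B": 0.0, "C": -A, "D": params.E_eff / eta}
    raise ValueError(f"unknown model {model}")  # pragma: no cover


def inverse_capillary_velocity(eta: float, gamma: float) -> float:
    """eta/gamma in s/um: the timescale per unit length of capillary-driven
    shape relaxation (coalescing droplets relax with tau = (eta/gamma)*l).

    With eta in Pa*s and gamma in uN/m the ratio is in s/um exactly
    (1 Pa*s / 1 uN/m = 1 N*s*m^-2 / 1e-6 N*m^-1 = 1e6 s/m = 1 s/um).
    """
    if eta <= 0:
        raise ValueError(f"viscosity must be > 0, got {eta}")
    if gamma <= 0:
        raise ValueError(
            f"capillary velocity undefined for gamma <= 0, got {gamma}"
        )
    return eta / gamma
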