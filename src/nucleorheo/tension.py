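"""Interfacial tension from the pressure dependence of the flow coefficient.

For a Newtonian phase the fitted flow coefficient is B = (P - P_gamma)/eta, so
a weighted linear fit of B against applied pressure P vanishes exactly at
P = P_gamma: the pressure-axis intercept of the fit is the Laplace pressure of
all interfaces acting on the aspirated material.  Dividing by the curvature
term 2(1/Rp - 1/Rc) converts it to an interfacial tension.  When two
interfaces contribute (e.g. an outer droplet surface plus an internal
subcompartment boundary), the apparent tension decomposes additively and the
inner tension is recovered by subtracting the known outer one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .models import InvalidGeometryError

__all__ = [
    "PressureSeries",
    "TensionEstimate",
    "fit_B_vs_pressure",
    "tension_from_laplace",
    "estimate_tension",
    "composite_tension_subtract",
    "cohort_tension",
]


@dataclass
class PressureSeries:
    """Flow coefficients B (1/s) measured at several applied pressures (Pa).

    Each entry is (P, B, se_B, trace_id); at least three distinct pressures
    are required for the two-parameter line to be identified.  ``Rp``/``Rc``
    are the pipette and outer-droplet radii (um) used to convert the inferred
    Laplace pressure to a tension.
    """

    entries: List[Tuple[float, float, float, str]]
    Rp: float
    Rc: float = math.inf
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if len({p for p, *_ in self.entries}) < 3:
            raise ValueError(
                "need B at >= 3 distinct pressures to infer the intercept"
            )
        if any(se <= 0 for _, _, se, _ in self.entries):
            raise ValueError("all se_B must be > 0 (they weight the fit)")
        if self.Rp <= 0:
            raise InvalidGeometryError(f"pipette radius must be > 0, got {self.Rp}")

    @property
    def P(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries], dtype=float)

    @property
    def B(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=float)

    @property
    def se_B(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=float)


@dataclass
class TensionEstimate:
    """Inferred Laplace pressure and interfacial tension for one sample."""

    sample_id: str
    laplace_pressure: float  # Pa
    laplace_pressure_err: float
    gamma: float  # uN/m
    gamma_err: float
    slope: float  # 1/(s*Pa) -> 1/eta_eff
    slope_err: float
    n_pressures: int


class NonPhysicalSeriesError(ValueError):
    """Flow coefficient does not increase with pressure."""


def fit_B_vs_pressure(
    series: PressureSeries, *, weighting: str = "inverse_variance"
) -> Tuple[float, float, np.ndarray]:
    """Weighted least squares of B on P; returns (slope, P0, covariance).

    Weights are 1/se_B**2 (``weighting="inverse_variance"``, the
    conventional reading) or 1/se_B (``"inverse_se"``).  The returned ``P0``
    is the pressure-axis intercept -b/m, the pressure at which flow stops:
    the inferred Laplace pressure.  ``covariance`` is the 2x2 absolute
    covariance of (m, b) from the stated standard errors.
    """
    P, B, se = series.P, series.B, series.se_B
    if weighting == "inverse_variance":
        w = 1.0 / se**2
    elif weighting == "inverse_se":
        w = 1.0 / se
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    # WLS normal equations for B = m*P + b (equivalent to curve_fit with
    # sigma=se, absolute_sigma=True under inverse-variance weighting).
    X = np.column_stack([P, np.ones_like(P)])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    cov = np.linalg.inv(xtwx)
    m, b = cov @ (X.T @ (w * B))
    if m <= 0:
        raise NonPhysicalSeriesError(
            f"fitted slope {m:.3g} <= 0: flow must increase with pressure"
        )
    P0 = -b / m
    return float(m), float(P0), cov


def _p0_uncertainty(m: float, b: float, cov: np.ndarray) -> float:
    # First-order propagation of P0 = -b/m through the (m, b) covariance.
    dm = b / m**2
    db = -1.0 / m
    var = dm * dm * cov[0, 0] + db * db * cov[1, 1] + 2 * dm * db * cov[0, 1]
    return math.sqrt(max(var, 0.0))


def tension_from_laplace(P0: float, Rp: float, Rc: float = math.inf) -> float:
    """gamma = P0 / (2(1/Rp - 1/Rc)) in uN/m; exact inverse of the Laplace law."""
    if Rp <= 0:
        raise InvalidGeometryError(f"pipette radius must be > 0, got {Rp}")
    if not math.isinf(Rc) and Rc <= Rp:
        raise InvalidGeometryError(
            f"outer radius Rc={Rc} must exceed pipette radius Rp={Rp}"
        )
    inv_rc = 0.0 if math.isinf(Rc) else 1.0 / Rc
    return P0 / (2.0 * (1.0 / Rp - inv_rc))


def estimate_tension(
    series: PressureSeries, *, weighting: str = "inverse_variance"
) -> TensionEstimate:
    """Full per-sample inference: WLS fit, intercept, tension with uncertainty."""
    m, P0, cov = fit_B_vs_pressure(series, weighting=weighting)
    b = -P0 * m
    p0_err = _p0_uncertainty(m, b, cov)
    curv = 2.0 * (1.0 / series.Rp - (0.0 if math.isinf(series.Rc) else 1.0 / series.Rc))
    return TensionEstimate(
        sample_id=series.sample_id,
        laplace_pressure=P0,
        laplace_pressure_err=p0_err,
        gamma=P0 / curv,
        gamma_err=p0_err / curv,
        slope=m,
        slope_err=float(math.sqrt(cov[0, 0])),
        n_pressures=len({p for p, *_ in series.entries}),
    )


def cohort_tension(estimates: Sequence[TensionEstimate]) -> Tuple[float, float]:
    """Unweighted mean +/- SEM of per-sample tensions (NaN SEM for one sample)."""
    if not estimates:
        raise ValueError("no tension estimates to average")
    g = np.array([e.gamma for e in estimates], dtype=float)
    sem = float(np.std(g, ddof=1) / math.sqrt(len(g))) if len(g) > 1 else math.nan
    return float(g.mean()), sem


def composite_tension_subtract(
    gamma_apparent: float,
    gamma_outer: float,
    *,
    err_apparent: float = 0.0,
    err_outer: float = 0.0,
) -> Tuple[float, float, bool]:
    """Inner-interface tension from a composite (two-interface) measurement.

    Returns (gamma_inner, error in quadrature, consistent).  A negative
    difference is returned flagged (``consistent=False``), never clipped:
    it signals that the assumed outer tension exceeds the apparent total.
    """
    if gamma_outer < 0:
        raise ValueError("outer tension must be >= 0")
    inner = gamma_apparent - gamma_outer
    err = math.hypot(err_apparent, err_outer)
    return inner, err, inner >= 0
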