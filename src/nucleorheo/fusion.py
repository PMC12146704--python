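"""Coalescence analysis: aspect-ratio relaxation and capillary velocity.

Two droplets that have just fused relax from an elongated shape back to a
sphere under interfacial tension, resisted by viscosity.  The aspect ratio
decays exponentially,

    AR(t) = 1 + (AR0 - 1) * exp(-t / tau),

and the relaxation time scales with droplet size, tau = (eta/gamma) * l,
where l is the geometric mean of the major and minor axes at t = 0.  Fitting
tau against l across events therefore yields the inverse capillary velocity
eta/gamma (s/um) without measuring eta or gamma separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FusionEvent",
    "CapillaryVelocityFit",
    "fit_relaxation",
    "fit_capillary_velocity",
    "aspect_ratio_stats",
]


@dataclass
class FusionEvent:
    """Aspect-ratio time series of one coalescence event.

    t = 0 is the first frame at which the fused object is a single connected
    region.  Aspect ratios below 1 are flagged (measurement artifacts), never
    silently clipped.  ``length_scale`` l = sqrt(major0 * minor0) in um.
    """

    times: np.ndarray
    AR: np.ndarray
    major_axis0: float
    minor_axis0: float
    event_id: str = "event"
    AR0_fit: Optional[float] = None
    tau_fit: Optional[float] = None
    tau_err: Optional[float] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.AR = np.asarray(self.AR, dtype=float)
        if self.times.shape != self.AR.shape:
            raise ValueError("times and AR must have equal length")
        if self.major_axis0 <= 0 or self.minor_axis0 <= 0:
            raise ValueError("initial axes must be > 0")
        if self.major_axis0 < self.minor_axis0:
            raise ValueError("major axis must be >= minor axis")

    @property
    def length_scale(self) -> float:
        return math.sqrt(self.major_axis0 * self.minor_axis0)

    @property
    def subunity_flags(self) -> np.ndarray:
        return self.AR < 1.0


@dataclass
class CapillaryVelocityFit:
    """Through-origin fit of tau = (eta/gamma) * l across fusion events."""

    slope: float  # eta/gamma, s/um
    slope_err: float
    n_events: int
    residuals: np.ndarray
    intercept_fit: Tuple[float, float]  # diagnostic (slope, intercept), free intercept


class DegenerateEventError(ValueError):
    """Aspect ratio indistinguishable from 1; relaxation time undefined."""


def fit_relaxation(
    event: FusionEvent, *, noise_floor: float = 1e-3
) -> Tuple[float, float]:
    """Nonlinear least squares for (AR0, tau) on one event; updates the event.

    AR0 is constrained >= 1.  If the aspect-ratio excursion above 1 never
    exceeds ``noise_floor`` the relaxation time is undefined and the event is
    flagged degenerate (raises `DegenerateEventError`).
    """
    t = event.times - event.times[0]
    ar = event.AR
    if len(t) < 5:
        raise ValueError("need >= 5 time points to fit a relaxation")
    excursion = float(np.max(ar) - 1.0)
    if excursion < noise_floor:
        event.degenerate = True
        raise DegenerateEventError(
            f"event {event.event_id!r}: AR range {excursion:.2g} below noise "
            f"floor {noise_floor:.2g}; tau undefined"
        )

    def model(t, ar0, tau):
        return 1.0 + (ar0 - 1.0) * np.exp(-t / tau)

    # time to half of the initial excursion sets the tau scale
    half = 1.0 + 0.5 * (ar[0] - 1.0)
    below = np.nonzero(ar <= half)[0]
    tau0 = t[below[0]] / math.log(2.0) if len(below) and t[below[0]] > 0 else (t[-1] or 1.0)
    p0 = [max(ar[0], 1.0 + noise_floor), tau0]
    popt, pcov = curve_fit(
        model, t, ar, p0=p0, bounds=([1.0, 1e-12], [np.inf, np.inf]), maxfev=20000
    )
    ar0, tau = (float(v) for v in popt)
    event.AR0_fit = ar0
    event.tau_fit = tau
    with np.errstate(invalid="ignore"):
        event.tau_err = float(np.sqrt(pcov[1, 1]))
    return ar0, tau


def fit_capillary_velocity(
    events: Sequence[Tuple[float, float]] | Sequence[FusionEvent],
) -> CapillaryVelocityFit:
    """Least-squares slope of tau on l through the origin: eta/gamma in s/um.

    Accepts (tau, l) pairs or fitted `FusionEvent` objects.  The model
    tau = (eta/gamma)*l has no intercept, so the primary fit is constrained
    through the origin; a free-intercept diagnostic fit is also reported.
    """
    pairs: List[Tuple[float, float]] = []
    for e in events:
        if isinstance(e, FusionEvent):
            if e.tau_fit is None or e.degenerate:
                continue
            pairs.append((e.tau_fit, e.length_scale))
        else:
            pairs.append((float(e[0]), float(e[1])))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 valid events, got {len(pairs)}")
    tau = np.array([p[0] for p in pairs])
    l = np.array([p[1] for p in pairs])
    if np.any(l <= 0) or np.any(tau <= 0):
        raise ValueError("tau and l must be > 0")

    slope = float(np.sum(l * tau) / np.sum(l**2))
    resid = tau - slope * l
    dof = len(pairs) - 1
    s2 = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
    slope_err = math.sqrt(s2 / float(np.sum(l**2)))

    if np.ptp(l) > 0:
        m_free, b_free = np.polyfit(l, tau, 1)
    else:  # all events at one size: free-intercept line is unidentified
        m_free, b_free = math.nan, math.nan
    return CapillaryVelocityFit(
        slope=slope,
        slope_err=slope_err,
        n_events=len(pairs),
        residuals=resid,
        intercept_fit=(float(m_free), float(b_free)),
    )


def aspect_ratio_stats(
    ARs: Sequence[float], *, bins: int | Sequence[float] = 20
) -> Tuple[float, float, Tuple[np.ndarray, np.ndarray]]:
    """Mean, SEM and histogram of a population of aspect ratios.

    SEM is NaN for a single value (flagged undefined, not zero).
    """
    a = np.asarray(list(ARs), dtype=float)
    if a.size == 0:
        raise ValueError("empty aspect-ratio list")
    mean = float(a.mean())
    sem = float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else math.nan
    counts, edges = np.histogram(a, bins=bins)
    return mean, sem, (counts, edges)
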