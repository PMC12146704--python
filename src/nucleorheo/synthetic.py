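"""Ground-truth-known synthetic inputs for every analysis stage.

The generators emulate the study conditions of a micropipette-aspiration
campaign on multiphase nucleoli: stepped-pressure viscoelastic creep traces
with additive length noise, multi-pressure Newtonian series sharing a
Laplace-pressure offset, exponential aspect-ratio relaxation with relaxation
time proportional to droplet size, and kymograph images of an advancing
fluorescent front, optionally fragmented by a necking gap.

Phase presets carry the magnitudes measured for the nucleolar compartments:
the granular component (GC) as a Newtonian fluid of ~220 Pa*s, the dense
fibrillar component (DFC) as a Kelvin-Voigt solid (eta ~250 Pa*s,
E ~3.1 Pa), and the RNase-fluidized DFC as a Newtonian fluid of ~1000 Pa*s.
Tension presets: GC-nucleoplasm 1.7 uN/m, GC-DFC upper bound 0.5 uN/m,
RNase-treated composite 8.0 uN/m.  Imaging cadence defaults to 2 s/frame.

Every stochastic generator takes a mandatory seed; identical (seed, config)
produce bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .creep import AspirationTrace
from .fusion import FusionEvent
from .kymograph import Kymograph
from .models import (
    Interface,
    MaterialParams,
    ModelClass,
    StressContext,
    strain_response,
)
from .tension import PressureSeries

__all__ = [
    "PhasePreset",
    "PHASE_PRESETS",
    "TENSION_PRESETS",
    "DEFAULT_FRAME_INTERVAL",
    "simulate_aspiration_trace",
    "simulate_cohort",
    "simulate_pressure_series",
    "simulate_kymograph",
    "simulate_fusion_event",
]

DEFAULT_FRAME_INTERVAL = 2.0  # s/frame, dual-label imaging cadence


@dataclass(frozen=True)
class PhasePreset:
    """Generating truth for one nucleolar phase."""

    model: ModelClass
    eta: float  # Pa*s
    E: Optional[float] = None  # Pa
    gamma: float = 1.7  # uN/m, outermost interface

    def params(self) -> MaterialParams:
        return MaterialParams(eta_eff=self.eta, E_eff=self.E, gamma=self.gamma)


PHASE_PRESETS: Dict[str, PhasePreset] = {
    "GC": PhasePreset(ModelClass.NEWTONIAN, eta=220.0, gamma=1.7),
    "DFC": PhasePreset(ModelClass.KELVIN_VOIGT, eta=250.0, E=3.1, gamma=1.7),
    "DFC_RNase": PhasePreset(ModelClass.NEWTONIAN, eta=1000.0, gamma=8.0),
}

TENSION_PRESETS: Dict[str, float] = {
    "GC_nucleoplasm": 1.7,  # uN/m
    "GC_DFC_upper_bound": 0.5,
    "RNase_composite": 8.0,
}

# Measured viscosities vary by over two orders of magnitude across nucleoli;
# a lognormal sigma of 1.15 (base e) spans roughly that range over ~20 samples.
DEFAULT_COHORT_LOG_SD = 1.15


def _rng(seed: Optional[int]) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is mandatory for stochastic generation")
    return np.random.default_rng(seed)


def simulate_aspiration_trace(
    model: ModelClass,
    params: MaterialParams,
    ctx: StressContext,
    *,
    duration: float,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    Rp: float = 1.0,
    Rc: float = math.inf,
    L0: float = 2.0,
    phase: str = "GC",
    trace_id: str = "sim",
    nucleolus_id: str = "sim_nuc",
) -> AspirationTrace:
    """Constant-pressure creep trace: Lp_i = L0 + Rp*eps(sigma_eff, t_i) + noise.

    ``noise_sd`` is additive Gaussian noise on Lp in um (pixel-scale
    measurement error).  The first frame is the aspiration onset, so the
    noiseless trace satisfies compute_strain == strain_response exactly.
    With ``sigma_eff <= 0`` the generator warns and emits a non-advancing
    trace (capillarity exceeds suction).
    """
    times = np.arange(0.0, duration + 0.5 * frame_interval, frame_interval)
    sigma = ctx.effective_stress
    if sigma <= 0:
        warnings.warn(
            f"effective stress {sigma:.3g} Pa <= 0: capillarity exceeds "
            "suction; trace will not advance",
            stacklevel=2,
        )
        eps = np.zeros_like(times)
    else:
        eps = strain_response(model, params, sigma, times)
    Lp = L0 + Rp * np.asarray(eps)
    if noise_sd > 0:
        Lp = Lp + _rng(seed).normal(0.0, noise_sd, size=Lp.shape)
        Lp = np.clip(Lp, 0.0, None)
    return AspirationTrace(
        times=times,
        Lp=Lp,
        P=ctx.applied_pressure,
        Rp=Rp,
        Rc=Rc,
        phase=phase,
        trace_id=trace_id,
        nucleolus_id=nucleolus_id,
        L0=float(L0),
        metadata={
            "true_model": model.value,
            "true_eta": params.eta_eff,
            "true_E": params.E_eff,
            "sigma_eff": sigma,
        },
    )


def simulate_cohort(
    phase: str,
    *,
    n_nucleoli: int,
    traces_per_nucleolus: int = 1,
    P: float = 20.0,
    Rp: float = 1.0,
    Rc: float = math.inf,
    duration: float = 300.0,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    noise_sd: float = 0.0,
    cohort_log_sd: float = 0.0,
    seed: int = 0,
) -> List[AspirationTrace]:
    """A cohort of traces for one phase preset with optional biological
    dispersion (lognormal multiplier on eta per nucleolus;
    ``cohort_log_sd=DEFAULT_COHORT_LOG_SD`` spans ~2 orders of magnitude)."""
    preset = PHASE_PRESETS[phase]
    rng = _rng(seed)
    ctx = StressContext(
        applied_pressure=P, interfaces=(Interface(preset.gamma, Rp, Rc),)
    )
    traces = []
    for i in range(n_nucleoli):
        mult = float(np.exp(rng.normal(0.0, cohort_log_sd))) if cohort_log_sd else 1.0
        params = MaterialParams(
            eta_eff=preset.eta * mult, E_eff=preset.E, gamma=preset.gamma
        )
        for j in range(traces_per_nucleolus):
            traces.append(
                simulate_aspiration_trace(
                    preset.model,
                    params,
                    ctx,
                    duration=duration,
                    frame_interval=frame_interval,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(2**31 - 1)),
                    Rp=Rp,
                    Rc=Rc,
                    phase=phase,
                    trace_id=f"{phase}_n{i}_t{j}",
                    nucleolus_id=f"{phase}_n{i}",
                )
            )
    return traces


def simulate_pressure_series(
    pressures: Sequence[float],
    *,
    gamma: float,
    Rp: float,
    Rc: float = math.inf,
    eta: float,
    noise_sd_frac: float = 0.0,
    n_replicates: int = 1,
    seed: Optional[int] = None,
    sample_id: str = "sim_sample",
) -> PressureSeries:
    """Newtonian flow coefficients across pressures with a shared Laplace offset.

    B = (P - P_gamma)/eta with multiplicative Gaussian noise of fractional sd
    ``noise_sd_frac``; the reported se_B matches the generating noise level.
    All pressures must exceed the Laplace pressure (otherwise no flow).
    """
    from .models import laplace_pressure

    p_gamma = laplace_pressure(gamma, Rp, Rc)
    ps = [p for p in pressures for _ in range(n_replicates)]
    if all(p <= p_gamma for p in pressures):
        raise ValueError(
            f"all pressures <= Laplace pressure {p_gamma:.3g} Pa: no flow regime"
        )
    rng = _rng(seed) if noise_sd_frac > 0 else None
    entries = []
    for k, p in enumerate(ps):
        b_true = (p - p_gamma) / eta
        se = max(abs(b_true) * noise_sd_frac, 1e-12)
        b = b_true + (rng.normal(0.0, se) if rng is not None else 0.0)
        entries.append((float(p), float(b), float(se), f"{sample_id}_t{k}"))
    series = PressureSeries(entries=entries, Rp=Rp, Rc=Rc, sample_id=sample_id)
    return series


def simulate_kymograph(
    trace: AspirationTrace,
    *,
    pixel_size: float,
    intensity_in: float = 100.0,
    intensity_out: float = 10.0,
    noise_sd: float = 0.0,
    extent_px: Optional[int] = None,
    necking: Optional[Tuple[int, int, int]] = None,
    seed: Optional[int] = None,
    channel: str = "",
) -> Kymograph:
    """Render a trace as a step-profile kymograph (rows = frames).

    Each row is ``intensity_in`` up to the front at Lp_i/pixel_size,
    ``intensity_out`` beyond, with the partially covered boundary pixel
    linearly mixed.  ``necking=(gap_px, start_frame, stop_frame)`` carves an
    intensity gap behind the front over [start_frame, stop_frame) — a
    detached slug.  Gaussian pixel noise is added last.
    """
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    front_px = trace.Lp / pixel_size
    width = extent_px or int(math.ceil(front_px.max())) + 5
    if front_px.max() > width:
        raise ValueError("front leaves the rendered extent; enlarge extent_px")
    n = len(front_px)
    img = np.full((n, width), intensity_out, dtype=float)
    cols = np.arange(width)
    for i, f in enumerate(front_px):
        full = cols + 1 <= f
        img[i, full] = intensity_in
        j = int(math.floor(f))
        if 0 <= j < width:
            cover = f - j
            img[i, j] = intensity_out + cover * (intensity_in - intensity_out)
    if necking is not None:
        gap_px, f0, f1 = necking
        for i in range(max(f0, 0), min(f1, n)):
            mid = int(front_px[i] / 2)
            g0 = max(mid - gap_px // 2, 1)
            img[i, g0 : g0 + gap_px] = intensity_out
    if noise_sd > 0:
        img = img + _rng(seed).normal(0.0, noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None)
    return Kymograph(
        intensity=img,
        pixel_size=pixel_size,
        frame_interval=float(np.diff(trace.times).mean()),
        channel=channel,
    )


def simulate_fusion_event(
    AR0: float,
    *,
    tau: Optional[float] = None,
    l: Optional[float] = None,
    inverse_capillary_velocity: Optional[float] = None,
    frame_interval: float = 30.0,
    duration: Optional[float] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    event_id: str = "sim_event",
) -> FusionEvent:
    """Exponential aspect-ratio relaxation of one coalescence event.

    ``tau`` can be given directly or derived as tau = (eta/gamma)*l.  The
    initial axes are set consistently with AR0 and l: major = l*sqrt(AR0),
    minor = l/sqrt(AR0), so sqrt(major*minor) = l.  Warns when the cadence
    undersamples the relaxation (tau < 2 frames).
    """
    if AR0 < 1:
        raise ValueError(f"initial aspect ratio must be >= 1, got {AR0}")
    if tau is None:
        if l is None or inverse_capillary_velocity is None:
            raise ValueError(
                "give tau directly or both l and inverse_capillary_velocity"
            )
        tau = inverse_capillary_velocity * l
    if tau <= 0:
        raise ValueError(f"relaxation time must be > 0, got {tau}")
    if l is None:
        l = 3.0
    if tau < 2 * frame_interval:
        warnings.warn(
            f"tau = {tau:.3g} s is under-resolved at {frame_interval:.3g} "
            "s/frame; fitted relaxation times will be unreliable",
            stacklevel=2,
        )
    if duration is None:
        duration = 5 * tau
    times = np.arange(0.0, duration + 0.5 * frame_interval, frame_interval)
    ar = 1.0 + (AR0 - 1.0) * np.exp(-times / tau)
    if noise_sd > 0:
        ar = ar + _rng(seed).normal(0.0, noise_sd, size=ar.shape)
    root = math.sqrt(AR0)
    return FusionEvent(
        times=times,
        AR=ar,
        major_axis0=l * root,
        minor_axis0=l / root,
        event_id=event_id,
    )
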