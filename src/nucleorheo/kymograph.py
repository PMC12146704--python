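"""Front tracking on fluorescence kymographs of the aspirated column.

A kymograph is a time-by-position intensity grid taken along the pipette
axis (rows = frames, column 0 = pipette tip).  The aspirated length Lp at
each frame is the far edge of the contiguous above-threshold run that starts
at the tip, refined to sub-pixel precision by linear interpolation of the
intensity across the edge.  Frames whose above-threshold region splits into
several runs indicate a necking (pinch-off) instability; traces showing
persistent gaps are flagged and excluded from creep fitting.

Coordinate convention: pixel i covers the half-open interval [i, i+1) in
pixel units, so a front at integer position k means pixels 0..k-1 are fully
inside the aspirated phase.  Pixel centers sit at i + 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from skimage.filters import threshold_otsu

from .creep import AspirationTrace

__all__ = [
    "Kymograph",
    "FrontTrack",
    "segment_front",
    "detect_necking",
    "track_to_trace",
]


@dataclass
class Kymograph:
    """Time-by-position intensity grid with calibration.

    ``pixel_size`` in um/px along the pipette axis, ``frame_interval`` in s.
    """

    intensity: np.ndarray
    pixel_size: float
    frame_interval: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be a 2-D grid")
        if self.intensity.shape[0] < 5:
            raise ValueError("kymograph needs >= 5 frames")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def extent_px(self) -> int:
        return self.intensity.shape[1]


@dataclass
class FrontTrack:
    """Per-frame front positions (pixel units) with contiguity diagnostics."""

    front_px: np.ndarray
    contiguous: np.ndarray  # per-frame: above-threshold region is one run
    empty: np.ndarray  # per-frame: no above-threshold pixel at the tip
    saturated: np.ndarray  # per-frame: every pixel above threshold
    necking_detected: bool
    threshold: float
    min_gap_px: int
    min_persist_frames: int


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def _subpixel_edge(row: np.ndarray, last_above: int, mask: np.ndarray) -> float:
    """Sub-pixel front: crossing of the intensity profile with the half-height
    between the plateau (median of above-threshold pixels) and the background
    (median of the rest), interpolated linearly between pixel centers.  For an
    ideal step with the edge at integer k this returns exactly k."""
    j = last_above
    if j + 1 >= len(row):
        return float(len(row))
    hi = float(np.median(row[mask])) if mask.any() else float(row[j])
    below = row[~mask]
    lo = float(np.median(below)) if below.size else float(row[j + 1])
    half = 0.5 * (hi + lo)
    # walk forward from the last above-threshold pixel to the half-height crossing
    k = j
    while k + 1 < len(row) and row[k + 1] >= half:
        k += 1
    if k + 1 >= len(row):
        return float(len(row))
    a, b = row[k], row[k + 1]
    if a <= b or a < half:  # no clean falling edge; fall back to the pixel edge
        return float(j + 1)
    frac = (a - half) / (a - b)
    return float(k + 0.5 + np.clip(frac, 0.0, 1.0))


def segment_front(
    kymo: Kymograph,
    method: str = "otsu",
    *,
    fixed_fraction: float = 0.5,
    min_gap_px: int = 2,
    min_persist_frames: int = 2,
) -> FrontTrack:
    """Binarize each frame and track the far edge of the tip-attached run.

    ``method="otsu"`` uses a single Otsu threshold for the whole kymograph
    (per-kymograph rather than per-frame, to avoid frame-to-frame threshold
    jitter); ``"fixed_fraction"`` thresholds at
    min + fixed_fraction*(max - min).  Both are invariant to multiplying all
    intensities by a positive constant.

    A frame with no above-threshold pixel at the tip records front 0 with an
    ``empty`` flag; a fully saturated frame records the grid extent with a
    ``saturated`` flag.  Gap-based necking detection follows `detect_necking`.
    """
    img = kymo.intensity
    if method == "otsu":
        if np.ptp(img) == 0:
            thr = float(img.flat[0])  # flat image: nothing to separate
        else:
            thr = float(threshold_otsu(img))
    elif method == "fixed_fraction":
        if not 0 < fixed_fraction < 1:
            raise ValueError("fixed_fraction must be in (0, 1)")
        thr = float(img.min() + fixed_fraction * np.ptp(img))
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    n, width = img.shape
    front = np.zeros(n)
    contiguous = np.ones(n, dtype=bool)
    empty = np.zeros(n, dtype=bool)
    saturated = np.zeros(n, dtype=bool)

    for i in range(n):
        row = img[i]
        mask = row > thr
        runs = _runs(mask)
        if not runs or runs[0][0] != 0:
            empty[i] = True
            front[i] = 0.0
            continue
        if runs[0][1] == width and len(runs) == 1:
            saturated[i] = True
            front[i] = float(width)
            continue
        last_above = runs[0][1] - 1
        front[i] = _subpixel_edge(row, last_above, mask)
        if len(runs) > 1:
            # only gaps at least min_gap_px wide count as a genuine split
            gaps = [runs[k + 1][0] - runs[k][1] for k in range(len(runs) - 1)]
            if any(g >= min_gap_px for g in gaps):
                contiguous[i] = False

    track = FrontTrack(
        front_px=front,
        contiguous=contiguous,
        empty=empty,
        saturated=saturated,
        necking_detected=False,
        threshold=thr,
        min_gap_px=min_gap_px,
        min_persist_frames=min_persist_frames,
    )
    track.necking_detected = detect_necking(track)
    return track


def detect_necking(track: FrontTrack, min_persist_frames: Optional[int] = None) -> bool:
    """True iff a qualifying gap (>= min_gap_px wide, applied during
    segmentation) persists for at least ``min_persist_frames`` consecutive
    frames.  Single-frame flicker gaps do not count."""
    persist = min_persist_frames or track.min_persist_frames
    split = ~track.contiguous
    run = 0
    for s in split:
        run = run + 1 if s else 0
        if run >= persist:
            return True
    return False


def track_to_trace(
    track: FrontTrack,
    kymo: Kymograph,
    *,
    P: float,
    Rp: float,
    Rc: float = math.inf,
    phase: str = "GC",
    trace_id: str = "trace",
    nucleolus_id: str = "nucleolus",
    onset_frame: int = 0,
    metadata: Optional[dict] = None,
) -> AspirationTrace:
    """Calibrate a front track into an aspiration trace.

    Pixel positions become um via ``pixel_size`` and frame indices become s
    via ``frame_interval``; L0 is the front at ``onset_frame`` (the first
    frame after pressure onset) and the necking decision is carried into the
    trace's exclusion flag.
    """
    if len(track.front_px) != kymo.n_frames:
        raise ValueError("track and kymograph frame counts disagree")
    sl = slice(onset_frame, None)
    Lp = track.front_px[sl] * kymo.pixel_size
    times = np.arange(kymo.n_frames)[sl] * kymo.frame_interval
    return AspirationTrace(
        times=times,
        Lp=Lp,
        P=P,
        Rp=Rp,
        Rc=Rc,
        phase=phase,
        trace_id=trace_id,
        nucleolus_id=nucleolus_id,
        L0=float(Lp[0]),
        necking_flag=track.necking_detected,
        metadata=metadata or {},
    )
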