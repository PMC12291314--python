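"""Double-normalized fluorescence bands and donor/acceptor-side group statistics.

A band normalizes the trace between the origin F0 and a phase-reference
landmark: W = (Ft - F0) / (Fref - F0), with Fref = FJ for the O-J phase,
FK for O-K and FI for O-I. Treatment-minus-control difference bands
(delta-W) expose the K band (~300 µs, OEC damage) and L band (~150 µs).

Group curves are averaged after per-replicate normalization (mean of W,
not W of the mean trace), on a common 200-point log-time grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError, SingularParameterError, UsageError
from .io import FluorescenceTransient
from .jip import (
    DEFAULT_T0_US,
    JIPParameters,
    OJIPLandmarks,
    extract_landmarks,
    interp_log_time,
)

__all__ = [
    "NormalizedBand",
    "PHASE_REFERENCE_TIME_US",
    "normalize_band",
    "mean_band",
    "delta_band",
    "k_band_statistics",
    "w_oi_tail_amplitude",
    "oec_centers",
    "qa_reducing_centers",
    "band_frame",
]

#: Reference time (µs) whose landmark anchors W = 1 for each phase.
PHASE_REFERENCE_TIME_US = {"OJ": 2_000.0, "OK": 300.0, "OI": 30_000.0}

RESAMPLE_POINTS = 200


@dataclass
class NormalizedBand:
    """A double-normalized curve on one phase window, or its delta form."""

    phase: str
    times: np.ndarray
    W: np.ndarray
    is_delta: bool = False
    reference_group: str | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASE_REFERENCE_TIME_US:
            raise UsageError(f"unknown phase {self.phase!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.times.shape != self.W.shape:
            raise UsageError("times and W must have the same shape")


def _reference_value(landmarks: OJIPLandmarks, phase: str) -> float:
    return {"OJ": landmarks.FJ, "OK": landmarks.FK, "OI": landmarks.FI}[phase]


def normalize_band(
    transient: FluorescenceTransient,
    landmarks: OJIPLandmarks,
    phase: str,
) -> NormalizedBand:
    """Compute W = (Ft - F0)/(Fref - F0) on the phase window.

    Windows run from the landmark origin t0 to 2 ms (OJ), 300 µs (OK) or
    the end of the trace (OI). The origin and reference times are inserted
    into the grid (log-time interpolated) so the curve passes through
    (t0, 0) and (t_ref, 1) exactly.
    """
    if phase not in PHASE_REFERENCE_TIME_US:
        raise UsageError(f"unknown phase {phase!r}")
    f_ref = _reference_value(landmarks, phase)
    if f_ref <= landmarks.F0:
        raise NormalizationError(
            f"phase {phase}: reference landmark {f_ref:g} <= F0 {landmarks.F0:g}"
        )
    t0 = landmarks.t0
    t_ref = PHASE_REFERENCE_TIME_US[phase]
    t_end = transient.times[-1] if phase == "OI" else t_ref
    t, f = transient.times, transient.fluorescence

    mask = (t > t0) & (t < t_end)
    grid = np.unique(np.concatenate(([t0, t_ref], t[mask], [t_end])))
    grid = grid[(grid >= t0) & (grid <= t_end)]
    ft = interp_log_time(t, f, grid)
    W = (ft - landmarks.F0) / (f_ref - landmarks.F0)
    # pin the anchors exactly (interpolation already hits them up to fp noise)
    W[grid == t0] = 0.0
    W[grid == t_ref] = 1.0
    return NormalizedBand(phase=phase, times=grid, W=W)


def _phase_grid(phase: str, t0: float, t_end: float, n: int = RESAMPLE_POINTS) -> np.ndarray:
    return np.geomspace(t0, t_end, n)


def mean_band(bands: Sequence[NormalizedBand], n_points: int = RESAMPLE_POINTS) -> NormalizedBand:
    """Average replicate bands on a common log-time grid."""
    if not bands:
        raise UsageError("mean_band: empty band list")
    phase = bands[0].phase
    if any(b.phase != phase for b in bands):
        raise UsageError("mean_band: mixed phases")
    if any(b.is_delta for b in bands):
        raise UsageError("mean_band: cannot average delta bands")
    t0 = max(b.times[0] for b in bands)
    t_end = min(b.times[-1] for b in bands)
    grid = _phase_grid(phase, t0, t_end, n_points)
    t_ref = PHASE_REFERENCE_TIME_US[phase]
    grid = np.unique(np.concatenate((grid, [t_ref])))
    W = np.mean([interp_log_time(b.times, b.W, grid) for b in bands], axis=0)
    return NormalizedBand(phase=phase, times=grid, W=W)


def delta_band(
    treated: NormalizedBand,
    control: NormalizedBand,
    reference_group: str = "control",
) -> NormalizedBand:
    """delta-W(t) = W_treated(t) - W_control(t) on a common grid."""
    if treated.phase != control.phase:
        raise UsageError(
            f"phase mismatch: {treated.phase} vs {control.phase}"
        )
    if treated.times.shape == control.times.shape and np.allclose(
        treated.times, control.times
    ):
        grid = treated.times
        dW = treated.W - control.W
    else:
        t0 = max(treated.times[0], control.times[0])
        t_end = min(treated.times[-1], control.times[-1])
        grid = _phase_grid(treated.phase, t0, t_end)
        dW = interp_log_time(treated.times, treated.W, grid) - interp_log_time(
            control.times, control.W, grid
        )
    return NormalizedBand(
        phase=treated.phase, times=grid, W=dW, is_delta=True, reference_group=reference_group
    )


def k_band_statistics(
    group: Sequence[FluorescenceTransient],
    control: Sequence[FluorescenceTransient],
    t0: float = DEFAULT_T0_US,
) -> tuple[float, float]:
    """Mean VK of the group and its shift versus control (delta-VK)."""
    if not group or not control:
        raise UsageError("k_band_statistics: empty group")

    def vk(trs: Sequence[FluorescenceTransient]) -> float:
        vals = []
        for tr in trs:
            lm = extract_landmarks(tr, t0=t0)
            vals.append((lm.FK - lm.F0) / (lm.Fm - lm.F0))
        return float(np.mean(vals))

    vk_group = vk(group)
    return vk_group, vk_group - vk(control)


def w_oi_tail_amplitude(band: NormalizedBand) -> float:
    """Amplitude of the W_OI >= 1 fraction: max over t >= 30 ms of (W - 1), floored at 0."""
    if band.phase != "OI":
        raise UsageError(f"w_oi_tail_amplitude needs an OI band, got {band.phase}")
    mask = band.times >= PHASE_REFERENCE_TIME_US["OI"]
    if not mask.any():
        raise UsageError("band has no samples at or beyond 30 ms")
    return float(max(0.0, np.max(band.W[mask]) - 1.0))


def _mean_attr(params: Iterable[JIPParameters], attr: str) -> float:
    vals = [getattr(p, attr) for p in params]
    if not vals:
        raise UsageError(f"empty parameter group for {attr}")
    return float(np.mean(vals))


def oec_centers(
    treated: Sequence[JIPParameters], control: Sequence[JIPParameters]
) -> float:
    """Active fraction of oxygen-evolving-complex centers.

    (1 - VK/VJ)_treated / (1 - VK/VJ)_control, each factor evaluated on the
    group-mean VK and VJ.
    """

    def factor(params: Sequence[JIPParameters], label: str) -> float:
        vj = _mean_attr(params, "VJ")
        if vj == 0:
            raise SingularParameterError("VJ", f"{label}: mean VJ = 0")
        return 1.0 - _mean_attr(params, "VK") / vj

    num = factor(treated, "treated")
    den = factor(control, "control")
    if den == 0:
        raise SingularParameterError("OEC centers", "control (1 - VK/VJ) = 0")
    return num / den


def qa_reducing_centers(
    treated: Sequence[JIPParameters],
    control: Sequence[JIPParameters],
    mode: str = "quotient",
) -> float:
    """Fraction of Q_A-reducing reaction centers versus control.

    Combines the treated/control ratios of RC/CSm and ABS/CSm (group means).
    ``mode`` selects how the two bracketed ratios combine: ``"quotient"``
    (default) divides, ``"product"`` multiplies.
    """
    if mode not in ("quotient", "product"):
        raise UsageError(f"unknown mode {mode!r}")
    rc_c = _mean_attr(control, "RC_CSm")
    abs_c = _mean_attr(control, "ABS_CSm")
    if rc_c == 0 or abs_c == 0:
        raise SingularParameterError("QA-RC", "control RC/CSm or ABS/CSm is zero")
    rc_ratio = _mean_attr(treated, "RC_CSm") / rc_c
    abs_ratio = _mean_attr(treated, "ABS_CSm") / abs_c
    if mode == "quotient":
        if abs_ratio == 0:
            raise SingularParameterError("QA-RC", "ABS/CSm ratio is zero")
        return rc_ratio / abs_ratio
    return rc_ratio * abs_ratio


def band_frame(
    band: NormalizedBand, variety: str, treatment: str
) -> pd.DataFrame:
    """Export one band as rows of the band CSV dialect."""
    col = "delta_W" if band.is_delta else "W"
    return pd.DataFrame(
        {
            "phase": band.phase,
            "variety": variety,
            "treatment": treatment,
            "time_us": band.times,
            col: band.W,
        }
    )
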