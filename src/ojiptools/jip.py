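"""OJIP landmark extraction and the algebraic JIP-test parameter set.

Landmarks are read off the trace by linear interpolation in log10(time):
the instrument samples log-uniformly and the transient is near-linear in
log time between steps. ``Fm`` is the global trace maximum. ``F0`` is taken
at a configurable origin time (default 20 µs, the PEA-class convention).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTransientError, ExtractionError, SingularParameterError
from .io import FluorescenceTransient, GroupTable

__all__ = [
    "OJIPLandmarks",
    "JIPParameters",
    "LANDMARK_TIMES_US",
    "DEFAULT_T0_US",
    "extract_landmarks",
    "relative_variable_fluorescence",
    "compute_jip_parameters",
    "jip_parameter_table",
]

#: Nominal landmark times (µs): L, K, J, I steps.
LANDMARK_TIMES_US = {"L": 150.0, "K": 300.0, "J": 2_000.0, "I": 30_000.0}
DEFAULT_T0_US = 20.0


@dataclass(frozen=True)
class OJIPLandmarks:
    """Fluorescence values at the origin, L/K/J/I steps and the P maximum."""

    F0: float
    FL: float
    FK: float
    FJ: float
    FI: float
    Fm: float
    t_Fm: float
    t0: float = DEFAULT_T0_US

    def __post_init__(self) -> None:
        vals = {"F0": self.F0, "FL": self.FL, "FK": self.FK, "FJ": self.FJ, "FI": self.FI, "Fm": self.Fm}
        for name, v in vals.items():
            if not np.isfinite(v) or v <= 0:
                raise DegenerateTransientError(f"landmark {name} must be finite and > 0, got {v!r}")
            if name != "Fm" and v > self.Fm:
                raise DegenerateTransientError(f"landmark {name}={v:g} exceeds Fm={self.Fm:g}")
        if self.F0 >= self.Fm:
            raise DegenerateTransientError(
                f"flat transient: F0={self.F0:g} >= Fm={self.Fm:g}"
            )


def interp_log_time(times: np.ndarray, values: np.ndarray, at: float | np.ndarray):
    """Linear interpolation of ``values`` against log10(times) at time(s) ``at``."""
    return np.interp(np.log10(at), np.log10(times), values)


def extract_landmarks(
    transient: FluorescenceTransient, t0: float = DEFAULT_T0_US
) -> OJIPLandmarks:
    """Extract F0/FL/FK/FJ/FI/Fm from one trace.

    ``t0`` must lie within [first sample, 50 µs]. Raises
    :class:`ExtractionError` if a nominal time falls outside the trace
    support, and :class:`DegenerateTransientError` if the maximum sits at
    the first sample (no rise).
    """
    t, f = transient.times, transient.fluorescence
    if not (t[0] <= t0 <= 50.0):
        raise ExtractionError(
            f"t0={t0:g} µs outside [{t[0]:g}, 50] µs for "
            f"{transient.variety}/{transient.treatment}/rep{transient.replicate}"
        )
    for name, t_nom in LANDMARK_TIMES_US.items():
        if not (t[0] <= t_nom <= t[-1]):
            raise ExtractionError(
                f"{name}-step time {t_nom:g} µs outside trace support [{t[0]:g}, {t[-1]:g}]"
            )
    i_max = int(np.argmax(f))
    if i_max == 0:
        raise DegenerateTransientError(
            f"maximum at first sample for "
            f"{transient.variety}/{transient.treatment}/rep{transient.replicate}"
        )
    f0, fl, fk, fj, fi = interp_log_time(
        t, f, np.array([t0, *LANDMARK_TIMES_US.values()])
    )
    return OJIPLandmarks(
        F0=float(f0), FL=float(fl), FK=float(fk), FJ=float(fj), FI=float(fi),
        Fm=float(f[i_max]), t_Fm=float(t[i_max]), t0=float(t0),
    )


def relative_variable_fluorescence(landmarks: OJIPLandmarks, Ft: float) -> float:
    """Vt = (Ft - F0) / (Fm - F0)."""
    span = landmarks.Fm - landmarks.F0
    if span == 0:
        raise SingularParameterError("Fm - F0", "Fm equals F0; Vt undefined")
    return (Ft - landmarks.F0) / span


# GroupTable trait names, in canonical output order.
JIP_TRAITS = (
    "VL", "VK", "VJ", "VI", "M0",
    "phiPo", "psiEo", "phiEo", "deltaRo", "phiRo",
    "ABS_RC", "TR0_RC", "ET0_RC", "DI0_RC", "RE0_RC",
    "ABS_CSm", "TR0_CSm", "ET0_CSm", "DI0_CSm", "RC_CSm",
    "PIabs", "PItotal",
)


@dataclass(frozen=True)
class JIPParameters:
    """The derived JIP-test quantities for one transient.

    Relative variable fluorescence at the four steps (VL..VI), the initial
    slope proxy M0 = 4*VK, quantum yields/efficiencies, specific fluxes per
    active reaction center, phenomenological fluxes per excited cross
    section (ABS/CSm approximated by Fm), and the two performance indices.
    """

    VL: float
    VK: float
    VJ: float
    VI: float
    M0: float
    phiPo: float
    psiEo: float
    phiEo: float
    deltaRo: float
    phiRo: float
    ABS_RC: float
    TR0_RC: float
    ET0_RC: float
    DI0_RC: float
    RE0_RC: float
    ABS_CSm: float
    TR0_CSm: float
    ET0_CSm: float
    DI0_CSm: float
    RC_CSm: float
    PIabs: float
    PItotal: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_jip_parameters(landmarks: OJIPLandmarks) -> JIPParameters:
    """Full JIP-test chain from one landmark set.

    Raises :class:`SingularParameterError` naming the offending quantity
    when a yield or relative fluorescence hits a pole (VJ in {0,1}, VI = 1,
    phiPo in {0,1}, deltaRo = 1).
    """
    lm = landmarks
    VL = relative_variable_fluorescence(lm, lm.FL)
    VK = relative_variable_fluorescence(lm, lm.FK)
    VJ = relative_variable_fluorescence(lm, lm.FJ)
    VI = relative_variable_fluorescence(lm, lm.FI)

    if VJ in (0.0, 1.0):
        raise SingularParameterError("VJ", f"VJ={VJ:g} makes the flux chain singular")
    if VI == 1.0:
        raise SingularParameterError("VI", "VI=1 makes deltaRo/RE0_RC singular")

    M0 = 4.0 * (lm.FK - lm.F0) / (lm.Fm - lm.F0)
    if M0 == 0.0:
        raise SingularParameterError("M0", "M0=0 (FK=F0): zero trapping flux")
    phiPo = 1.0 - lm.F0 / lm.Fm
    if phiPo in (0.0, 1.0):
        raise SingularParameterError("phiPo", f"phiPo={phiPo:g}")
    psiEo = 1.0 - VJ
    phiEo = phiPo * psiEo
    deltaRo = (1.0 - VI) / (1.0 - VJ)
    phiRo = phiPo * (1.0 - VI)

    TR0_RC = M0 / VJ
    ABS_RC = TR0_RC / phiPo
    ET0_RC = TR0_RC * (1.0 - VJ)
    DI0_RC = ABS_RC - TR0_RC
    RE0_RC = ET0_RC * deltaRo  # = TR0_RC * (1 - VI); this form keeps the identity exact

    ABS_CSm = lm.Fm
    TR0_CSm = phiPo * ABS_CSm
    ET0_CSm = phiEo * ABS_CSm
    DI0_CSm = ABS_CSm - TR0_CSm
    RC_CSm = phiPo * (VJ / M0) * ABS_CSm

    PIabs = (phiPo * VJ / M0) * (phiPo / (1.0 - phiPo)) * (psiEo / (1.0 - psiEo))
    if deltaRo == 1.0:
        raise SingularParameterError("deltaRo", "deltaRo=1 makes PItotal singular")
    PItotal = PIabs * deltaRo / (1.0 - deltaRo)

    return JIPParameters(
        VL=VL, VK=VK, VJ=VJ, VI=VI, M0=M0,
        phiPo=phiPo, psiEo=psiEo, phiEo=phiEo, deltaRo=deltaRo, phiRo=phiRo,
        ABS_RC=ABS_RC, TR0_RC=TR0_RC, ET0_RC=ET0_RC, DI0_RC=DI0_RC, RE0_RC=RE0_RC,
        ABS_CSm=ABS_CSm, TR0_CSm=TR0_CSm, ET0_CSm=ET0_CSm, DI0_CSm=DI0_CSm,
        RC_CSm=RC_CSm, PIabs=PIabs, PItotal=PItotal,
    )


def jip_parameter_table(
    transients: Iterable[FluorescenceTransient], t0: float = DEFAULT_T0_US
) -> GroupTable:
    """Compute JIP parameters for every transient and return them as a tidy table."""
    records = []
    for tr in transients:
        params = compute_jip_parameters(extract_landmarks(tr, t0=t0))
        for trait in JIP_TRAITS:
            records.append(
                (tr.variety, tr.treatment, tr.replicate, trait, getattr(params, trait))
            )
    return GroupTable(
        pd.DataFrame.from_records(
            records, columns=["variety", "treatment", "replicate", "trait", "value"]
        )
    )


def landmark_table(
    transients: Sequence[FluorescenceTransient], t0: float = DEFAULT_T0_US
) -> pd.DataFrame:
    """Landmark values per replicate as a flat DataFrame (for reporting)."""
    rows = []
    for tr in transients:
        lm = extract_landmarks(tr, t0=t0)
        rows.append(
            {
                "variety": tr.variety,
                "treatment": tr.treatment,
                "replicate": tr.replicate,
                "F0": lm.F0, "FL": lm.FL, "FK": lm.FK,
                "FJ": lm.FJ, "FI": lm.FI, "Fm": lm.Fm, "t_Fm": lm.t_Fm,
            }
        )
    return pd.DataFrame(rows)
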