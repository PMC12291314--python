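"""Pigment quantification, water-use efficiency and percent-change arithmetic.

Chlorophyll and carotenoid contents follow the Lichtenthaler
spectrophotometric system for 95% ethanol extracts. The equations operate
on extract concentrations (µg mL^-1); the volume/fresh-weight factor
V / (1000 W) then converts to mg per g fresh weight — including inside the
carotenoid equation, whose embedded chlorophyll terms are concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PigmentAbsorbances",
    "PigmentContents",
    "PigmentWarning",
    "pigments_from_absorbance",
    "water_use_efficiency",
    "percent_change",
]


class PigmentWarning(UserWarning):
    """A computed pigment concentration came out negative (bad readings)."""


@dataclass(frozen=True)
class PigmentAbsorbances:
    """Extract absorbances at 665/649/470 nm plus extraction geometry."""

    A665: float
    A649: float
    A470: float
    extract_volume_ml: float
    fresh_weight_g: float

    def __post_init__(self) -> None:
        for name in ("A665", "A649", "A470"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not (np.isfinite(self.extract_volume_ml) and self.extract_volume_ml > 0):
            raise ValueError("extract_volume_ml must be > 0")
        if not (np.isfinite(self.fresh_weight_g) and self.fresh_weight_g > 0):
            raise ValueError("fresh_weight_g must be > 0")


@dataclass(frozen=True)
class PigmentContents:
    """Pigment contents in mg per g fresh weight; chl_ab = chl_a + chl_b."""

    chl_a: float
    chl_b: float
    chl_ab: float
    car: float
    chl_ab_ratio: float


def pigments_from_absorbance(a: PigmentAbsorbances) -> PigmentContents:
    """Chl a, Chl b, Chl a+b and carotenoid contents from absorbance readings.

    Concentrations (µg mL^-1)::

        Ca  = 13.95 A665 - 6.88 A649
        Cb  = 24.96 A649 - 7.32 A665
        Car = (1000 A470 - 2.05 Ca - 114.8 Cb) / 245

    each converted to mg g^-1 by the factor V / (1000 W). Negative
    concentrations are kept (not clipped) and flagged with
    :class:`PigmentWarning`.
    """
    ca = 13.95 * a.A665 - 6.88 * a.A649
    cb = 24.96 * a.A649 - 7.32 * a.A665
    car = (1000.0 * a.A470 - 2.05 * ca - 114.8 * cb) / 245.0
    if min(ca, cb, car) < 0:
        warnings.warn(
            f"negative pigment concentration (Ca={ca:g}, Cb={cb:g}, Car={car:g} µg/mL)",
            PigmentWarning,
            stacklevel=2,
        )
    to_content = a.extract_volume_ml / (1000.0 * a.fresh_weight_g)
    chl_a = ca * to_content
    chl_b = cb * to_content
    ratio = chl_a / chl_b if chl_b != 0 else float("nan")
    return PigmentContents(
        chl_a=chl_a,
        chl_b=chl_b,
        chl_ab=chl_a + chl_b,
        car=car * to_content,
        chl_ab_ratio=ratio,
    )


def water_use_efficiency(Pn: float, Tr: float) -> float:
    """WUE = Pn / Tr (µmol CO2 per mmol H2O)."""
    if not (np.isfinite(Tr) and Tr > 0):
        raise ValueError(f"Tr must be > 0, got {Tr!r}")
    return Pn / Tr


def percent_change(value: float, reference: float) -> float:
    """100 * (value - reference) / reference; negative means decline."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (value - reference) / reference
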