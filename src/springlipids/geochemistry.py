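"""Spring geochemistry: sample records, the neutrality line, unit handling.

Neutral pH is temperature dependent: pure water at 0 °C is neutral near pH
7.47 and the neutral point falls with temperature because Kw rises. The
quadratic neutrality line implemented here is defined on 0-100 °C and is
used to separate acidic from alkaline springs when a temperature-aware
split is wanted; the conventional fixed pH-7.0 split is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .lipid_indices import LipidProfile

#: molar masses (g/mol) used to convert field mass concentrations to mol/L.
#: Sulphide is reported as S (Hach colorimetric basis).
MOLAR_MASS: dict[str, float] = {
    "sulfide": 32.06,
    "fe2": 55.845,
}

#: multiplicative factor from a mass-concentration unit to g/L
_UNIT_TO_G_PER_L = {
    "g/L": 1.0,
    "mg/L": 1e-3,
    "ug/L": 1e-6,
    "µg/L": 1e-6,
    "μg/L": 1e-6,
}

#: field detection limits, in mol/L (5 μg/L sulphide-as-S; 0.01 mg/L Fe)
DETECTION_LIMIT_M: dict[str, float] = {
    "sulfide": 5e-6 / MOLAR_MASS["sulfide"],
    "fe2": 0.01e-3 / MOLAR_MASS["fe2"],
}


def neutral_ph(
    temperature: float, allow_extrapolation: bool = False
) -> float:
    """pH of water's neutral point at the given temperature (°C).

    Evaluates ``8e-5·T² − 0.0208·T + 7.4692``, defined on [0, 100] °C;
    outside that window the call is refused unless ``allow_extrapolation``.
    """
    t = float(temperature)
    if not allow_extrapolation and not (0.0 <= t <= 100.0):
        raise ValueError(
            f"temperature {t} °C outside the neutrality line's domain "
            "[0, 100] °C (pass allow_extrapolation=True to override)"
        )
    return 8e-5 * t * t - 0.0208 * t + 7.4692


def classify_acidity(
    ph: float,
    temperature: Optional[float] = None,
    mode: str = "fixed7",
) -> str:
    """Label a spring 'acidic' or 'alkaline'.

    ``fixed7``: acidic iff pH < 7.0 (alkaline at exactly 7.0).
    ``neutrality_line``: acidic iff pH < neutral_ph(temperature).
    """
    if ph is None or (isinstance(ph, float) and np.isnan(ph)):
        raise ValueError("classification requires pH")
    if mode == "fixed7":
        threshold = 7.0
    elif mode == "neutrality_line":
        if temperature is None or (
            isinstance(temperature, float) and np.isnan(temperature)
        ):
            raise ValueError("neutrality_line mode requires temperature")
        threshold = neutral_ph(temperature)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return "acidic" if ph < threshold else "alkaline"


def to_molar(value: float, analyte: str, unit: str = "g/L") -> float:
    """Convert a mass concentration of a configured analyte to mol/L."""
    if analyte not in MOLAR_MASS:
        raise ValueError(
            f"unknown analyte {analyte!r}; known: {sorted(MOLAR_MASS)}"
        )
    if unit == "mol/L":
        return float(value)
    if unit not in _UNIT_TO_G_PER_L:
        raise ValueError(f"unknown unit {unit!r}")
    if value < 0:
        raise ValueError("concentration must be non-negative")
    return float(value) * _UNIT_TO_G_PER_L[unit] / MOLAR_MASS[analyte]


def impute_below_detection(
    analyte: str, strategy: str = "half_dl"
) -> Optional[float]:
    """Value (mol/L) substituted for a below-detection measurement.

    ``half_dl`` (common geochemical convention): half the detection limit;
    ``zero``: 0; ``exclude``: None (the record is dropped from analyses
    needing the analyte).
    """
    if strategy == "half_dl":
        return DETECTION_LIMIT_M[analyte] / 2.0
    if strategy == "zero":
        return 0.0
    if strategy == "exclude":
        return None
    raise ValueError(f"unknown imputation strategy {strategy!r}")


@dataclass
class SpringSample:
    """One thermal-spring record: site, geochemistry, and a lipid profile.

    Concentrations are in mol/L; ``spc`` in μS/cm; ``orp`` in mV. Optional
    analytes may be None; ``bd_flags`` records which were below the field
    detection limit before imputation.
    """

    site_id: str
    temperature: float
    ph: float
    profile: Optional[LipidProfile] = None
    source_study: str = ""
    do_conc: Optional[float] = None
    spc: Optional[float] = None
    orp: Optional[float] = None
    fe2: Optional[float] = None
    sulfide: Optional[float] = None
    fraction_label: str = "CL"
    bd_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.temperature <= 100.0):
            raise ValueError(
                f"{self.site_id}: temperature {self.temperature} outside "
                "[0, 100] °C"
            )
        if not (0.0 <= self.ph <= 14.0):
            raise ValueError(f"{self.site_id}: pH {self.ph} outside [0, 14]")
        for name in ("do_conc", "spc", "fe2", "sulfide"):
            v = getattr(self, name)
            if v is not None and v < 0 and not self.bd_flags.get(name):
                raise ValueError(f"{self.site_id}: negative {name}")
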