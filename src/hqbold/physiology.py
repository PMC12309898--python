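"""Oxygen transport model: inspired-oxygen conditions to blood saturations.

Converts arterial oxygen tension into arterial/capillary/venous oxygen
saturations and contents via the Severinghaus dissociation curve and a
mass-balance across the tissue bed.  The venous side keeps the dissolved
plasma component, so venous pO2 is obtained by root finding rather than by
inverting the hemoglobin term alone.

Units: pressures in mmHg, O2 contents in mLO2 dl^-1, saturations and
volume fractions dimensionless.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BloodGasConstants",
    "PhysiologicalState",
    "OxygenationState",
    "severinghaus_saturation",
    "severinghaus_inverse",
    "arterial_o2_content",
    "venous_oxygenation",
    "hyperoxia_pair",
    "load_constants",
]

_P_LO, _P_HI = 0.1, 5000.0  # bracket for pO2 root finds (mmHg)
_PTOL = 1e-9


class InfeasibleExtractionError(ValueError):
    """Metabolic O2 demand exceeds (or equals) the arterial O2 supply."""


@dataclass(frozen=True)
class BloodGasConstants:
    """Physical constants of oxygen carriage in blood.

    phi
        O2-carrying capacity of hemoglobin (mLO2 g^-1).
    hb
        Hemoglobin concentration (gHb dl^-1).
    epsilon
        Plasma O2 solubility (mLO2 dl^-1 mmHg^-1).
    kappa
        Arterial weighting of the capillary saturation
        Sc = kappa*Sa + (1-kappa)*Sv; kappa < 0.5 weights toward venous.
    t1b
        Longitudinal relaxation time of blood at 3 T (ms), used by TRUST.
    hct_large, hct_small
        Hematocrit in large vessels (TRUST calibration) and in the
        microvasculature (qBOLD susceptibility scaling).
    """

    phi: float = 1.34
    hb: float = 15.0
    epsilon: float = 0.0031
    kappa: float = 0.4
    t1b: float = 1624.0
    hct_large: float = 0.42
    hct_small: float = 0.34

    def __post_init__(self) -> None:
        for name in ("phi", "hb", "epsilon", "t1b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.kappa < 1:
            raise ValueError("kappa must lie in (0, 1)")
        for name in ("hct_large", "hct_small"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class PhysiologicalState:
    """The six sampled tissue/blood parameters defining one physiological state."""

    cbv_total: float = 0.05
    dbv: float = 0.023
    oef: float = 0.40
    hct: float = 0.34
    pao2_norm: float = 110.0
    pao2_hyper: float = 400.0

    def __post_init__(self) -> None:
        if not 0 <= self.dbv <= self.cbv_total:
            raise ValueError("require 0 <= dbv <= cbv_total")
        if not 0 <= self.oef <= 1:
            raise ValueError("oef must lie in [0, 1]")
        if self.pao2_hyper < self.pao2_norm:
            raise ValueError("pao2_hyper must be >= pao2_norm")
        if not 0 < self.hct < 1:
            raise ValueError("hct must lie in (0, 1)")


@dataclass(frozen=True)
class OxygenationState:
    """Derived saturations, tensions and O2 contents for one inspired-O2 level."""

    pao2: float
    pvo2: float
    sao2: float
    svo2: float
    sco2: float
    cao2: float
    cvo2: float
    cmeto2: float


def severinghaus_saturation(p):
    """Hemoglobin O2 saturation at partial pressure ``p`` (mmHg).

    Empirical dissociation curve S = (23400 (p^3 + 150 p)^-1 + 1)^-1,
    strictly increasing and bounded in (0, 1).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("partial pressure must be strictly positive")
    s = 1.0 / (23400.0 / (p**3 + 150.0 * p) + 1.0)
    return float(s) if s.ndim == 0 else s


def severinghaus_inverse(s: float) -> float:
    """Partial pressure (mmHg) at which hemoglobin saturation equals ``s``."""
    if not 0 < s < 1:
        raise ValueError("saturation must lie in (0, 1)")
    lo, hi = _P_LO, _P_HI
    if severinghaus_saturation(hi) < s:  # pragma: no cover - s ~ 1-1e-12
        raise ValueError("saturation too close to 1 to invert in bracket")
    return brentq(lambda p: severinghaus_saturation(p) - s, lo, hi, xtol=_PTOL)


def arterial_o2_content(
    pao2: float, constants: BloodGasConstants = BloodGasConstants()
) -> tuple[float, float]:
    """Arterial O2 content (hemoglobin-bound plus dissolved) and saturation.

    CaO2 = phi [Hb] SaO2 + epsilon PaO2.
    """
    sao2 = severinghaus_saturation(pao2)
    cao2 = constants.phi * constants.hb * sao2 + constants.epsilon * pao2
    return cao2, sao2


def venous_oxygenation(
    cao2: float, cmeto2: float, constants: BloodGasConstants = BloodGasConstants()
) -> tuple[float, float, float]:
    """Venous pO2, saturation and content after extraction of ``cmeto2``.

    Solves phi [Hb] S(pv) + epsilon pv = CaO2 - CmetO2 for the venous
    tension, keeping the dissolved plasma term (it is not negligible under
    hyperoxia).  Returns ``(pvo2, svo2, cvo2)``.
    """
    if cmeto2 < 0:
        raise ValueError("cmeto2 must be non-negative")
    if cmeto2 >= cao2:
        raise InfeasibleExtractionError(
            f"metabolic demand {cmeto2:.3f} >= arterial supply {cao2:.3f} mLO2/dl"
        )
    cvo2 = cao2 - cmeto2

    def residual(p: float) -> float:
        return (
            constants.phi * constants.hb * severinghaus_saturation(p)
            + constants.epsilon * p
            - cvo2
        )

    if residual(_P_LO) > 0:
        # cvo2 below the content at the lower bracket edge: unphysiological.
        raise InfeasibleExtractionError("venous content below model range")
    pvo2 = brentq(residual, _P_LO, _P_HI, xtol=_PTOL)
    return pvo2, severinghaus_saturation(pvo2), cvo2


def hyperoxia_pair(
    state: PhysiologicalState, constants: BloodGasConstants = BloodGasConstants()
) -> tuple[OxygenationState, OxygenationState]:
    """Oxygenation states at normoxia and hyperoxia for one tissue state.

    The metabolically extracted content CmetO2 = OEF * CaO2(normoxia) is held
    fixed across the two conditions: oxygen demand does not change with the
    inspired gas, so the extra arterial O2 carried under hyperoxia raises the
    venous saturation.  The capillary saturation is the weighted sum
    Sc = kappa Sa + (1-kappa) Sv.
    """
    cao2_n, sao2_n = arterial_o2_content(state.pao2_norm, constants)
    cmeto2 = state.oef * cao2_n

    def build(pao2: float) -> OxygenationState:
        cao2, sao2 = arterial_o2_content(pao2, constants)
        if cmeto2 == 0.0:
            pvo2, svo2, cvo2 = pao2, sao2, cao2
        else:
            pvo2, svo2, cvo2 = venous_oxygenation(cao2, cmeto2, constants)
        sco2 = constants.kappa * sao2 + (1.0 - constants.kappa) * svo2
        return OxygenationState(
            pao2=pao2, pvo2=pvo2, sao2=sao2, svo2=svo2, sco2=sco2,
            cao2=cao2, cvo2=cvo2, cmeto2=cmeto2,
        )

    return build(state.pao2_norm), build(state.pao2_hyper)


def load_constants(path: str | Path) -> BloodGasConstants:
    """Load :class:`BloodGasConstants` overrides from a YAML or JSON file.

    Unknown keys raise; unspecified fields keep their defaults.
    """
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("constants file must contain a mapping")
    valid = {f.name for f in dataclasses.fields(BloodGasConstants)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown constant(s): {sorted(unknown)}")
    return BloodGasConstants(**data)
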