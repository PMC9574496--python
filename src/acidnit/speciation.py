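"""Acid-base speciation of ammoniacal and nitrite nitrogen.

Total ammoniacal nitrogen (TAN = NH4+-N + NH3-N) and total nitrite nitrogen
(TNN = NO2--N + HNO2-N) are partitioned into their protonated and
deprotonated forms from pH, temperature and ionic strength.  The free,
uncharged species (NH3, HNO2) are the ones that cross cell membranes and
drive both microbial inhibition and abiotic nitrite chemistry, so getting
their fractions right matters more than anywhere else in this package.

Dissociation constants use the classical temperature functions

    pKa(NH4+)  = 0.09018 + 2729.92 / T[K]
    pKa(HNO2)  = 2300 / (T[K] * ln 10)          (from ln Ka = -2300 / T[K])

and single-ion activity coefficients follow the Davies equation, an
empirical extension of Debye-Hueckel theory valid to roughly I = 0.5 mol/L,
which covers urine-strength liquors.  pH is taken as the glass-electrode
reading, i.e. hydrogen-ion *activity*; activity corrections therefore apply
only to the ionic partner of each pair, the neutral species getting
gamma = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpeciationConstants",
    "IonicContext",
    "activity_coefficient",
    "ionic_strength_from_conductivity",
    "free_ammonia",
    "free_nitrous_acid",
    "speciate",
]

#: Empirical conversion from electrical conductivity (mS/cm) to ionic
#: strength (mol/L); the common rule-of-thumb for mixed-electrolyte waters.
DEFAULT_EC_TO_IONIC_STRENGTH = 0.016


def _pka_nh4(temperature_c: float, coeffs: tuple[float, float]) -> float:
    a, b = coeffs
    return a + b / (temperature_c + 273.15)


def _pka_hno2(temperature_c: float, coeffs: tuple[float]) -> float:
    (b,) = coeffs
    return b / ((temperature_c + 273.15) * math.log(10.0))


@dataclass(frozen=True)
class SpeciationConstants:
    """Dissociation-constant and activity-correction parameters.

    Attributes
    ----------
    pKa_NH4_coeffs
        ``(a, b)`` in ``pKa = a + b / T[K]`` for the ammonium pair.
    pKa_HNO2_coeffs
        ``(b,)`` in ``ln Ka = -b / T[K]`` for the nitrous-acid pair.
    davies_A
        Debye-Hueckel ``A`` coefficient (0.509 at 25 degC).
    davies_linear
        Coefficient of the linear ionic-strength term (0.3).
    """

    pKa_NH4_coeffs: tuple[float, float] = (0.09018, 2729.92)
    pKa_HNO2_coeffs: tuple[float, ...] = (2300.0,)
    davies_A: float = 0.509
    davies_linear: float = 0.3

    def __post_init__(self) -> None:
        if self.davies_A <= 0:
            raise ValueError("davies_A must be positive")

    def pKa_NH4(self, temperature_c: float) -> float:
        """Thermodynamic pKa of NH4+ at the given temperature (degC)."""
        return _pka_nh4(temperature_c, self.pKa_NH4_coeffs)

    def pKa_HNO2(self, temperature_c: float) -> float:
        """Thermodynamic pKa of HNO2 at the given temperature (degC)."""
        return _pka_hno2(temperature_c, self.pKa_HNO2_coeffs)


@dataclass(frozen=True)
class IonicContext:
    """Solution conditions for one speciation evaluation.

    ``ionic_strength`` may be given directly (mol/L) or estimated from
    ``conductivity`` (mS/cm) via :func:`ionic_strength_from_conductivity`.
    """

    ionic_strength: float | None = None
    temperature: float = 25.0
    conductivity: float | None = None
    ec_factor: float = field(default=DEFAULT_EC_TO_IONIC_STRENGTH)

    def __post_init__(self) -> None:
        if not (0.0 <= self.temperature <= 45.0):
            raise ValueError(
                f"temperature {self.temperature} degC outside the supported 0-45 degC"
            )
        if self.ionic_strength is not None and self.ionic_strength < 0:
            raise ValueError("ionic_strength must be non-negative")

    def resolve_ionic_strength(self) -> float:
        """Ionic strength in mol/L, from the explicit value or conductivity."""
        if self.ionic_strength is not None:
            return self.ionic_strength
        if self.conductivity is not None:
            return ionic_strength_from_conductivity(self.conductivity, self.ec_factor)
        return 0.0


def ionic_strength_from_conductivity(
    conductivity: float, factor: float = DEFAULT_EC_TO_IONIC_STRENGTH
) -> float:
    """Estimate ionic strength (mol/L) from conductivity (mS/cm).

    Uses the linear empirical rule ``I = factor * EC``; the default factor
    of 0.016 mol/L per mS/cm is a rule-of-thumb for mixed electrolytes and
    should be calibrated when the matrix composition is known.
    """
    if conductivity < 0:
        raise ValueError(f"conductivity must be non-negative, got {conductivity}")
    if factor <= 0:
        raise ValueError("factor must be positive")
    return factor * conductivity


def activity_coefficient(
    charge: int,
    ctx: IonicContext,
    consts: SpeciationConstants = SpeciationConstants(),
) -> float:
    """Single-ion activity coefficient from the Davies equation.

    gamma = 10**(-A * z**2 * (sqrt(I)/(1 + sqrt(I)) - c*I))

    Returns 1.0 for neutral species or at zero ionic strength.
    """
    ionic_strength = ctx.resolve_ionic_strength()
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if charge == 0 or ionic_strength == 0.0:
        return 1.0
    sqrt_i = math.sqrt(ionic_strength)
    exponent = -consts.davies_A * charge**2 * (
        sqrt_i / (1.0 + sqrt_i) - consts.davies_linear * ionic_strength
    )
    return 10.0**exponent


def _check_inputs(total: float, name: str, pH: float) -> None:
    if np.any(np.asarray(total) < 0):
        raise ValueError(f"{name} must be non-negative")
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH {pH} outside (0, 14)")


def free_ammonia(
    TAN: float,
    pH: float,
    ctx: IonicContext,
    consts: SpeciationConstants = SpeciationConstants(),
) -> float:
    """Free-ammonia nitrogen (NH3-N, mg-N/L) from TAN, pH, T and I.

    The conditional constant pKa' = pKa - log10(gamma_NH4+) shifts with
    ionic strength; the NH3 fraction is r/(1+r) with r = 10**(pH - pKa').
    Conservation NH3-N + NH4-N = TAN holds exactly by construction.
    """
    _check_inputs(TAN, "TAN", pH)
    pka = consts.pKa_NH4(ctx.temperature)
    gamma_nh4 = activity_coefficient(1, ctx, consts)
    pka_cond = pka - math.log10(gamma_nh4)
    r = 10.0 ** (pH - pka_cond)
    return TAN * r / (1.0 + r)


def free_nitrous_acid(
    TNN: float,
    pH: float,
    ctx: IonicContext,
    consts: SpeciationConstants = SpeciationConstants(),
) -> float:
    """Free nitrous acid nitrogen (HNO2-N, mg-N/L) from TNN, pH, T and I.

    The conditional constant pKa' = pKa + log10(gamma_NO2-) shifts with
    ionic strength; the HNO2 fraction is 1/(1 + 10**(pH - pKa')), strictly
    decreasing in pH.  HNO2-N + NO2-N = TNN holds exactly.
    """
    _check_inputs(TNN, "TNN", pH)
    pka = consts.pKa_HNO2(ctx.temperature)
    gamma_no2 = activity_coefficient(-1, ctx, consts)
    pka_cond = pka + math.log10(gamma_no2)
    return TNN / (1.0 + 10.0 ** (pH - pka_cond))


def speciate(
    TAN: float,
    TNN: float,
    pH: float,
    ctx: IonicContext,
    consts: SpeciationConstants = SpeciationConstants(),
) -> dict[str, float]:
    """All four N species (mg-N/L) for one solution state."""
    nh3 = free_ammonia(TAN, pH, ctx, consts)
    hno2 = free_nitrous_acid(TNN, pH, ctx, consts)
    return {
        "NH3_N": nh3,
        "NH4_N": TAN - nh3,
        "HNO2_N": hno2,
        "NO2_N": TNN - hno2,
    }
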