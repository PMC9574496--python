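"""Limitation and inhibition factors for ammonia-oxidizer activity.

Descriptive multipliers in [0, 1] of the kind used in activated-sludge
models to interpret short-term respirometric tests: non-competitive free
nitrous acid (HNO2) inhibition, Monod saturation for dissolved oxygen and
free ammonia, a threshold-linear salinity penalty, and relative activity as
a ratio of oxygen uptake rates (OUR).  The factors combine multiplicatively.

These are interpretation tools for activity data; the abiotic reactor model
in :mod:`acidnit.reactor` deliberately does not use them.  Note also that
HNO2 is reported to be irreversibly toxic at high concentrations — a
history-dependent effect this reversible factor cannot represent.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = [
    "ActivityParams",
    "ActivityFactors",
    "hno2_inhibition_factor",
    "do_limitation_factor",
    "nh3_limitation_factor",
    "salinity_factor",
    "relative_activity",
    "combined_activity",
    "evaluate_factors",
]


@dataclass(frozen=True)
class ActivityParams:
    """Half-saturation / inhibition constants and the salinity rule.

    ``K_S_DO`` defaults to 0.8 mg-O2/L, the affinity estimated for
    acid-tolerant ammonia oxidizers; ``K_I_HNO2`` defaults to 2.8 mg-N/L,
    the upper end of the range reported for common AOB; salinity starts to
    bite above 20 mS/cm with a configurable linear slope.
    """

    K_I_HNO2: float = 2.8
    K_S_DO: float = 0.8
    K_S_NH3: float = 0.001
    salinity_threshold: float = 20.0
    salinity_slope: float = 5.0  # % activity lost per mS/cm above threshold

    def __post_init__(self) -> None:
        for name in ("K_I_HNO2", "K_S_DO", "K_S_NH3", "salinity_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.salinity_slope < 0:
            raise ValueError("salinity_slope must be non-negative")


@dataclass(frozen=True)
class ActivityFactors:
    """One multiplier per mechanism, each in [0, 1]."""

    hno2: float = 1.0
    do: float = 1.0
    nh3: float = 1.0
    salinity: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"factor {f.name}={v} outside [0, 1]")

    def combined(self) -> float:
        return self.hno2 * self.do * self.nh3 * self.salinity


def hno2_inhibition_factor(S_HNO2: float, K_I: float) -> float:
    """Non-competitive HNO2 inhibition: K_I / (K_I + S).

    Percent inhibition is 100 * (1 - factor); with K_I = 2.8 mg-N/L a
    concentration of 30 mg-N/L inhibits 91%.
    """
    if S_HNO2 < 0:
        raise ValueError("HNO2 concentration must be non-negative")
    if K_I <= 0:
        raise ValueError("K_I must be positive")
    return K_I / (K_I + S_HNO2)


def do_limitation_factor(DO: float, K_S: float) -> float:
    """Monod oxygen limitation: DO / (K_S + DO)."""
    if DO < 0:
        raise ValueError("DO must be non-negative")
    if K_S <= 0:
        raise ValueError("K_S must be positive")
    return DO / (K_S + DO)


def nh3_limitation_factor(S_NH3: float, K_S: float) -> float:
    """Monod free-ammonia limitation: S / (K_S + S)."""
    if S_NH3 < 0:
        raise ValueError("NH3 concentration must be non-negative")
    if K_S <= 0:
        raise ValueError("K_S must be positive")
    return S_NH3 / (K_S + S_NH3)


def salinity_factor(EC: float, params: ActivityParams) -> float:
    """Threshold-linear salinity penalty on conductivity EC (mS/cm).

    Full activity up to the threshold, then a linear decline of
    ``salinity_slope`` percent per mS/cm, floored at zero.
    """
    if EC < 0:
        raise ValueError("conductivity must be non-negative")
    if EC <= params.salinity_threshold:
        return 1.0
    return max(0.0, 1.0 - params.salinity_slope / 100.0 * (EC - params.salinity_threshold))


def relative_activity(OUR_test: float, OUR_ref: float) -> float:
    """Activity relative to the unperturbed reference OUR."""
    if OUR_ref <= 0:
        raise ValueError("reference OUR must be positive")
    if OUR_test < 0:
        raise ValueError("test OUR must be non-negative")
    return OUR_test / OUR_ref


def combined_activity(factors: ActivityFactors) -> float:
    """Product of all mechanism factors (activated-sludge-model convention)."""
    return factors.combined()


def evaluate_factors(
    S_HNO2: float,
    DO: float,
    S_NH3: float,
    EC: float,
    params: ActivityParams = ActivityParams(),
) -> ActivityFactors:
    """All factors for one set of conditions."""
    return ActivityFactors(
        hno2=hno2_inhibition_factor(S_HNO2, params.K_I_HNO2),
        do=do_limitation_factor(DO, params.K_S_DO),
        nh3=nh3_limitation_factor(S_NH3, params.K_S_NH3),
        salinity=salinity_factor(EC, params),
    )
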