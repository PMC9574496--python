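"""Chemical nitrite oxidation: rate laws, stoichiometry, gas stripping.

At acidic pH, nitrite leaves the biological realm: free nitrous acid
disproportionates to nitric oxide and nitrogen dioxide, NO is oxidized by
dissolved oxygen back to NO2, and NO2 hydrolyses to nitrite and nitrate.
The net effect is abiotic nitrate production plus loss of volatile nitrogen
oxides.  The reaction network implemented here is

    (R2)  2 HNO2        <->  NO + NO2 + H2O
    (R3)  2 NO + O2      ->  2 NO2
    (R4)  2 NO2 + H2O   <->  HNO2 + NO3- + H+
    (R5/6) NO + NO2 (as N2O3) + NH3 -> N2 + HNO2 + H2O

All reactions follow mass action in molar units.  N2O3 is not carried as a
state variable: it is treated as a quasi-steady intermediate formed from
NO + NO2, partitioned between decomposition (back to NO + NO2, a null
cycle) and reaction with NH3 according to a saturating branching fraction.

Nitrogen bookkeeping is exact by construction: every reaction maps to a
zero-sum redistribution over {TAN, TNN, NO3, NO(aq), NO2(aq), N2}, so a
closed system conserves total N to integrator precision.

Units: concentrations mg-N/L (DO in mg-O2/L), time in days.  Conversion to
mol/L happens only inside the rate-law evaluation.

The default rate constants are literature-sourced placeholders for nitrous
acid chemistry in acidic solution (flagged in :class:`ChemKineticsParams`);
every quantitative claim this package makes is independent of their values,
and any serious application should recalibrate them against measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .speciation import IonicContext, SpeciationConstants, free_ammonia, free_nitrous_acid

__all__ = [
    "MG_N_PER_MOL",
    "SolutionState",
    "ChemKineticsParams",
    "GasTransferParams",
    "RateVector",
    "reaction_rates",
    "species_derivatives",
    "strip_gas",
    "integrate_batch",
    "BatchTrajectory",
]

logger = logging.getLogger(__name__)

#: mg of nitrogen per mol of N.
MG_N_PER_MOL = 14006.7
#: mg of O2 per mol.
MG_O2_PER_MOL = 32000.0

_SECONDS_PER_DAY = 86400.0


@dataclass
class SolutionState:
    """Dissolved composition at one instant.

    All nitrogen pools in mg-N/L.  Free NH3 and HNO2 are never stored: they
    are derived from (TAN, pH) and (TNN, pH) through the speciation module,
    so speciation conservation can never be violated by state drift.
    ``N2_cum`` is pure bookkeeping of N2 produced by the ammonia branch.
    """

    TAN: float = 0.0
    TNN: float = 0.0
    NO3_N: float = 0.0
    NO_aq: float = 0.0
    NO2g_aq: float = 0.0
    N2_cum: float = 0.0
    DO: float = 5.0
    pH: float = 5.0
    temperature: float = 25.0
    ionic_strength: float = 0.0

    def validate(self) -> None:
        for name in ("TAN", "TNN", "NO3_N", "NO_aq", "NO2g_aq", "N2_cum", "DO"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")

    @property
    def total_N(self) -> float:
        """Total nitrogen over all pools incl. N2 bookkeeping (mg-N/L)."""
        return self.TAN + self.TNN + self.NO3_N + self.NO_aq + self.NO2g_aq + self.N2_cum

    def ionic_context(self) -> IonicContext:
        return IonicContext(ionic_strength=self.ionic_strength, temperature=self.temperature)


@dataclass(frozen=True)
class ChemKineticsParams:
    """Rate constants for the nitrite-oxidation network.

    Reaction rates are *event* rates (mol reaction events / L / d); the
    stoichiometric mapping to species is applied downstream.  Units are
    recorded per constant in :attr:`units`.

    The defaults are literature-sourced placeholders for nitrous-acid
    chemistry in acid solution (verify against Udert et al. (2005) before
    quantitative use):

    * ``k2_fwd``  — 2 HNO2 -> NO + NO2, second order in HNO2.
    * ``k2_rev``  — NO + NO2 + H2O -> 2 HNO2.
    * ``k3``      — 2 NO + O2 -> 2 NO2, third order overall.
    * ``k4_fwd``  — 2 NO2 hydrolysis, second order in NO2.
    * ``k4_rev``  — comproportionation HNO2 + NO3- + H+; negligible by
      default but kept so (R4) is formally reversible.
    * ``k_n2o3``  — N2O3 formation flux from NO + NO2.
    * ``K_nh3_branch`` — half-saturation of the NH3 branch: the fraction of
      N2O3 reacting with NH3 rather than decomposing is
      ``K*[NH3] / (1 + K*[NH3])``.
    * ``theta_*`` — Arrhenius-style temperature factors ``theta**(T-25)``
      per reaction; 1.0 disables the correction (constants are at 25 degC).
    """

    k2_fwd: float = 13.4 * _SECONDS_PER_DAY          # L/(mol d)
    k2_rev: float = 1.6e8 * _SECONDS_PER_DAY         # L/(mol d)
    k3: float = 2.1e6 * _SECONDS_PER_DAY             # L^2/(mol^2 d)
    k4_fwd: float = 1.0e8 * _SECONDS_PER_DAY         # L/(mol d)
    k4_rev: float = 1.0                              # L^2/(mol^2 d)
    k_n2o3: float = 1.1e9 * _SECONDS_PER_DAY         # L/(mol d)
    K_nh3_branch: float = 10.0                       # L/mol
    nh3_branch_enabled: bool = True
    theta_2: float = 1.0
    theta_3: float = 1.0
    theta_4: float = 1.0
    theta_56: float = 1.0
    units: tuple[tuple[str, str], ...] = (
        ("k2_fwd", "L mol-1 d-1"),
        ("k2_rev", "L mol-1 d-1"),
        ("k3", "L2 mol-2 d-1"),
        ("k4_fwd", "L mol-1 d-1"),
        ("k4_rev", "L2 mol-2 d-1"),
        ("k_n2o3", "L mol-1 d-1"),
        ("K_nh3_branch", "L mol-1"),
    )

    def __post_init__(self) -> None:
        for name in ("k2_fwd", "k2_rev", "k3", "k4_fwd", "k4_rev", "k_n2o3", "K_nh3_branch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_constants(self, **kwargs: float) -> "ChemKineticsParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GasTransferParams:
    """First-order gas-liquid stripping of NO and NO2.

    Off-gas partial pressures are assumed zero (open, vigorously aerated
    reactor), so the flux is ``kLa * C``.  When aeration is off, turbulence
    collapses and the flux is scaled by ``aeration_off_factor``.
    """

    kLa_NO: float = 100.0
    kLa_NO2: float = 100.0
    aeration_off_factor: float = 0.1

    def __post_init__(self) -> None:
        if self.kLa_NO < 0 or self.kLa_NO2 < 0:
            raise ValueError("kLa must be non-negative")
        if not (0.0 <= self.aeration_off_factor <= 1.0):
            raise ValueError("aeration_off_factor must lie in [0, 1]")


@dataclass(frozen=True)
class RateVector:
    """Signed reaction rates, mg-N/(L d) of each reaction's reference species.

    * ``r2`` — net HNO2-N consumption by (R2); negative when recombination wins.
    * ``r3`` — NO-N consumption by (R3); non-negative.
    * ``r4`` — net NO2-N consumption by (R4).
    * ``r56`` — N2-N production through the N2O3 + NH3 branch; non-negative.
    * ``strip_NO`` / ``strip_NO2`` — gas fluxes out of solution, mg-N/(L d).
    """

    r2: float
    r3: float
    r4: float
    r56: float
    strip_NO: float = 0.0
    strip_NO2: float = 0.0


def _arrhenius(theta: float, temperature: float) -> float:
    return theta ** (temperature - 25.0)


def reaction_rates(
    state: SolutionState,
    params: ChemKineticsParams,
    speciation: SpeciationConstants = SpeciationConstants(),
) -> RateVector:
    """Mass-action rates of (R2)-(R5/6) for one solution state.

    Free HNO2 and NH3 are computed from the totals via the speciation
    module; H+ enters (R4 reverse) as the activity 10**(-pH).
    """
    state.validate()
    ctx = state.ionic_context()
    hno2 = free_nitrous_acid(state.TNN, state.pH, ctx, speciation) / MG_N_PER_MOL
    nh3 = free_ammonia(state.TAN, state.pH, ctx, speciation) / MG_N_PER_MOL
    no = state.NO_aq / MG_N_PER_MOL
    no2 = state.NO2g_aq / MG_N_PER_MOL
    o2 = state.DO / MG_O2_PER_MOL
    h_activity = 10.0 ** (-state.pH)

    f2 = _arrhenius(params.theta_2, state.temperature)
    f3 = _arrhenius(params.theta_3, state.temperature)
    f4 = _arrhenius(params.theta_4, state.temperature)
    f56 = _arrhenius(params.theta_56, state.temperature)

    # event rates, mol/(L d)
    ev2 = f2 * (params.k2_fwd * hno2**2 - params.k2_rev * no * no2)
    ev3 = f3 * params.k3 * no**2 * o2
    ev4 = f4 * (params.k4_fwd * no2**2 - params.k4_rev * hno2 * state.NO3_N / MG_N_PER_MOL * h_activity)
    if params.nh3_branch_enabled:
        branch = params.K_nh3_branch * nh3 / (1.0 + params.K_nh3_branch * nh3)
        ev56 = f56 * params.k_n2o3 * no * no2 * branch
    else:
        ev56 = 0.0

    return RateVector(
        r2=2.0 * MG_N_PER_MOL * ev2,
        r3=2.0 * MG_N_PER_MOL * ev3,
        r4=2.0 * MG_N_PER_MOL * ev4,
        r56=2.0 * MG_N_PER_MOL * ev56,
    )


def strip_gas(
    state: SolutionState, gas: GasTransferParams, aerated: bool = True
) -> tuple[float, float]:
    """Stripping fluxes (NO, NO2) out of solution in mg-N/(L d)."""
    state.validate()
    factor = 1.0 if aerated else gas.aeration_off_factor
    return (factor * gas.kLa_NO * state.NO_aq, factor * gas.kLa_NO2 * state.NO2g_aq)


def species_derivatives(
    state: SolutionState,
    params: ChemKineticsParams,
    gas: GasTransferParams | None = None,
    aerated: bool = True,
    speciation: SpeciationConstants = SpeciationConstants(),
) -> dict[str, float]:
    """Time derivatives of all N pools, mg-N/(L d).

    Stoichiometric mapping (per mg-N of reference species):

    * (R2): TNN -r2, NO +r2/2, NO2 +r2/2
    * (R3): NO -r3, NO2 +r3
    * (R4): NO2 -r4, TNN +r4/2, NO3 +r4/2
    * (R5/6): NO -r56/2, NO2 -r56/2, TAN -r56/2, TNN +r56/2, N2 +r56

    The N-weighted sum of all derivatives (including gas fluxes and the N2
    ledger) is identically zero, so a closed system conserves nitrogen.
    """
    rates = reaction_rates(state, params, speciation)
    if gas is not None:
        s_no, s_no2 = strip_gas(state, gas, aerated)
    else:
        s_no = s_no2 = 0.0
    half56 = 0.5 * rates.r56
    return {
        "TAN": -half56,
        "TNN": -rates.r2 + 0.5 * rates.r4 + half56,
        "NO3_N": 0.5 * rates.r4,
        "NO_aq": 0.5 * rates.r2 - rates.r3 - half56 - s_no,
        "NO2g_aq": 0.5 * rates.r2 + rates.r3 - rates.r4 - half56 - s_no2,
        "N2_cum": rates.r56,
        "strip_NO": s_no,
        "strip_NO2": s_no2,
    }


_BATCH_SPECIES = ("TAN", "TNN", "NO3_N", "NO_aq", "NO2g_aq", "N2_cum")


@dataclass
class BatchTrajectory:
    """Closed-vessel integration output on the requested time grid."""

    time: np.ndarray
    species: dict[str, np.ndarray]
    stripped_NO: np.ndarray
    stripped_NO2: np.ndarray
    solver_stats: dict

    def state_at(self, i: int, template: SolutionState) -> SolutionState:
        s = replace(template)
        for name in _BATCH_SPECIES:
            setattr(s, name, float(self.species[name][i]))
        return s


def integrate_batch(
    state0: SolutionState,
    params: ChemKineticsParams,
    gas: GasTransferParams | None = None,
    t_end: float = 1.0,
    aerated: bool = True,
    speciation: SpeciationConstants = SpeciationConstants(),
    rtol: float = 1e-6,
    atol: float = 1e-9,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
) -> BatchTrajectory:
    """Integrate the closed (no-flow) chemistry from ``state0`` to ``t_end`` days.

    pH, DO, temperature and ionic strength are held at their initial values
    (drivers, not solved states).  The integrator is stiff-capable; sub-atol
    negative excursions are clipped to zero with a logged warning.

    Raises
    ------
    RuntimeError
        If the integrator fails; the message carries the last valid time.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    state0.validate()

    template = replace(state0)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        s = replace(template)
        for name, val in zip(_BATCH_SPECIES, y[:6]):
            setattr(s, name, max(val, 0.0))
        d = species_derivatives(s, params, gas, aerated, speciation)
        return np.array(
            [d["TAN"], d["TNN"], d["NO3_N"], d["NO_aq"], d["NO2g_aq"], d["N2_cum"],
             d["strip_NO"], d["strip_NO2"]]
        )

    y0 = np.array([getattr(state0, n) for n in _BATCH_SPECIES] + [0.0, 0.0])
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 101)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(
            f"chemistry integration failed at t={last_t:.6g} d: {sol.message}; "
            f"last state {dict(zip(_BATCH_SPECIES, sol.y[:6, -1])) if sol.t.size else y0[:6]}"
        )
    y = sol.y
    neg = y < 0
    if np.any(neg):
        worst = float(y[neg].min())
        if worst < -atol:
            logger.warning("clipping negative excursion down to %.3e to zero", worst)
        y = np.clip(y, 0.0, None)
    return BatchTrajectory(
        time=sol.t,
        species={name: y[i] for i, name in enumerate(_BATCH_SPECIES)},
        stripped_NO=y[6],
        stripped_NO2=y[7],
        solver_stats={"nfev": sol.nfev, "njev": sol.njev, "status": sol.status},
    )
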