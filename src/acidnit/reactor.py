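"""Driven CSTR simulation of abiotic nitrogen chemistry.

The reactor model mirrors how acidic ammonia-oxidation reactors are
analysed when the question is "can chemistry alone explain the nitrate?":
everything biological is reduced to a single imposed conversion — a
fraction ``f_ox`` of the incoming ammoniacal nitrogen appears as nitrite —
and pH, dissolved oxygen and temperature are *measured drivers* read from
an :class:`OperationTimeline`, never solved for.  On top of that sit the
chemical nitrite-oxidation network and first-order stripping of NO and NO2
from :mod:`acidnit.kinetics`.

For every dissolved species C the mass balance is

    dC/dt = (Q/V) (C_in - C) + r_source + r_chem - r_strip

with cumulative influent, effluent and stripped masses integrated inside
the same ODE system so the whole-run nitrogen balance closes to solver
tolerance by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (
    ChemKineticsParams,
    GasTransferParams,
    SolutionState,
    species_derivatives,
)
from .metrics import FitReport, NitrogenBalance, fit_report
from .speciation import SpeciationConstants, ionic_strength_from_conductivity

__all__ = [
    "OperationTimeline",
    "SimulationResult",
    "nitrite_source_rate",
    "simulate",
    "fit_to_measurements",
    "TIMELINE_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Canonical CSV column order for operation timelines.
TIMELINE_COLUMNS = ("time_d", "Q_L_per_d", "TAN_in_mgN_L", "pH", "DO_mg_L", "T_C", "EC_mS_cm")

#: DO (mg/L) below which the reactor counts as non-aerated for stripping.
AERATION_DO_THRESHOLD = 0.5


@dataclass
class OperationTimeline:
    """Exogenous reactor drivers on a strictly increasing time grid.

    ``Q`` and ``f_ox`` are control/pump signals and are interpolated with a
    zero-order hold; ``pH``, ``DO``, ``temperature`` and ``conductivity``
    are slowly varying measurements and are interpolated linearly.
    ``f_ox`` — the fraction of influent TAN oxidized to nitrite — may be a
    scalar (typically ~0.5 for alkalinity-limited urine) or a series.
    """

    time: np.ndarray
    Q: np.ndarray
    TAN_in: np.ndarray
    pH: np.ndarray
    DO: np.ndarray
    temperature: np.ndarray
    conductivity: np.ndarray
    volume: float = 12.0
    f_ox: float | np.ndarray = 0.5

    def __post_init__(self) -> None:
        arrays = {}
        n = len(self.time)
        for name in ("time", "Q", "TAN_in", "pH", "DO", "temperature", "conductivity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must be a 1-D array of length {n}")
            arrays[name] = arr
            setattr(self, name, arr)
        if np.isscalar(self.f_ox) or np.ndim(self.f_ox) == 0:
            self.f_ox = float(self.f_ox)
        else:
            self.f_ox = np.asarray(self.f_ox, dtype=float)
            if self.f_ox.shape != (n,):
                raise ValueError("f_ox series must match the time grid")
        self.validate()

    def validate(self) -> None:
        if len(self.time) < 2:
            raise ValueError("timeline needs at least two samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.Q < 0):
            raise ValueError("flow rate Q must be non-negative")
        if np.any(self.TAN_in < 0):
            raise ValueError("influent TAN must be non-negative")
        if self.volume <= 0:
            raise ValueError("reactor volume must be positive")
        fox = np.atleast_1d(self.f_ox)
        if np.any((fox < 0) | (fox > 1)):
            raise ValueError("f_ox must lie in [0, 1]")

    # -- driver interpolation -------------------------------------------------

    def _zoh(self, series: np.ndarray, t: float) -> float:
        i = np.searchsorted(self.time, t, side="right") - 1
        return float(series[np.clip(i, 0, len(series) - 1)])

    def Q_at(self, t: float) -> float:
        return self._zoh(self.Q, t)

    def f_ox_at(self, t: float) -> float:
        if isinstance(self.f_ox, float):
            return self.f_ox
        return self._zoh(self.f_ox, t)

    def TAN_in_at(self, t: float) -> float:
        return self._zoh(self.TAN_in, t)

    def pH_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.pH))

    def DO_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.DO))

    def temperature_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.temperature))

    def conductivity_at(self, t: float) -> float:
        return float(np.interp(t, self.time, self.conductivity))

    # -- CSV dialect ----------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_d": self.time,
                "Q_L_per_d": self.Q,
                "TAN_in_mgN_L": self.TAN_in,
                "pH": self.pH,
                "DO_mg_L": self.DO,
                "T_C": self.temperature,
                "EC_mS_cm": self.conductivity,
            }
        )
        if not isinstance(self.f_ox, float):
            df["f_ox"] = self.f_ox
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, volume: float = 12.0, f_ox: float | None = None
    ) -> "OperationTimeline":
        missing = [c for c in TIMELINE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"timeline CSV missing columns: {missing}")
        if f_ox is None:
            f_ox = df["f_ox"].to_numpy() if "f_ox" in df.columns else 0.5
        return cls(
            time=df["time_d"].to_numpy(),
            Q=df["Q_L_per_d"].to_numpy(),
            TAN_in=df["TAN_in_mgN_L"].to_numpy(),
            pH=df["pH"].to_numpy(),
            DO=df["DO_mg_L"].to_numpy(),
            temperature=df["T_C"].to_numpy(),
            conductivity=df["EC_mS_cm"].to_numpy(),
            volume=volume,
            f_ox=f_ox,
        )

    @classmethod
    def from_csv(cls, path, volume: float = 12.0, f_ox: float | None = None) -> "OperationTimeline":
        return cls.from_dataframe(pd.read_csv(path), volume=volume, f_ox=f_ox)


def nitrite_source_rate(timeline: OperationTimeline, t: float) -> float:
    """Imposed ammonia-to-nitrite conversion rate at time ``t``, mg-N/(L d).

    source = f_ox(t) * Q(t) * TAN_in(t) / V.  The same nitrogen is removed
    from the TAN pool, so the conversion itself conserves N exactly.
    """
    return timeline.f_ox_at(t) * timeline.Q_at(t) * timeline.TAN_in_at(t) / timeline.volume


_SPECIES = ("TAN", "TNN", "NO3_N", "NO_aq", "NO2g_aq")


@dataclass
class SimulationResult:
    """Species trajectories plus the cumulative nitrogen ledger.

    Cumulative quantities are in mg-N (whole reactor): ``stripped_NO`` /
    ``stripped_NO2`` left through the gas phase, ``n2_produced`` through the
    N2O3 + NH3 branch, ``influent_N`` entered, ``effluent_N`` left with the
    overflow.  ``nitrogen_balance()`` assembles the closure check.
    """

    time: np.ndarray
    species: dict[str, np.ndarray]
    stripped_NO: np.ndarray
    stripped_NO2: np.ndarray
    n2_produced: np.ndarray
    influent_N: np.ndarray
    effluent_N: np.ndarray
    volume: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def TNN(self) -> np.ndarray:
        return self.species["TNN"]

    @property
    def NO3_N(self) -> np.ndarray:
        return self.species["NO3_N"]

    def dissolved_storage_N(self, i: int) -> float:
        """Dissolved N inventory (mg-N) at output index ``i``."""
        return self.volume * float(sum(self.species[s][i] for s in _SPECIES))

    def gaseous_loss_N(self) -> float:
        """Total N lost to the gas phase over the run (mg-N)."""
        return float(self.stripped_NO[-1] + self.stripped_NO2[-1] + self.n2_produced[-1])

    def nitrogen_balance(self) -> NitrogenBalance:
        return NitrogenBalance(
            influent=float(self.influent_N[-1]),
            effluent=float(self.effluent_N[-1]),
            storage_change=self.dissolved_storage_N(len(self.time) - 1)
            - self.dissolved_storage_N(0),
            gaseous=self.gaseous_loss_N(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_d": self.time})
        for name in _SPECIES:
            df[f"{name}_mgN_L"] = self.species[name]
        df["stripped_NO_mgN"] = self.stripped_NO
        df["stripped_NO2_mgN"] = self.stripped_NO2
        df["N2_produced_mgN"] = self.n2_produced
        df["influent_N_mgN"] = self.influent_N
        df["effluent_N_mgN"] = self.effluent_N
        return df


def simulate(
    timeline: OperationTimeline,
    chem: ChemKineticsParams = ChemKineticsParams(),
    gas: GasTransferParams = GasTransferParams(),
    speciation: SpeciationConstants = SpeciationConstants(),
    initial_state: SolutionState | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "LSODA",
    ec_to_ionic_strength: float = 0.016,
) -> SimulationResult:
    """Run the driven CSTR over the timeline horizon.

    pH, DO, temperature and conductivity are read from the timeline at every
    step; the only influent species is TAN, of which the fraction ``f_ox``
    enters the nitrite pool (the imposed biological nitritation).  Initial
    condition defaults to nitrogen-free water at the timeline's start pH/T.
    """
    timeline.validate()
    if initial_state is None:
        initial_state = SolutionState()
    initial_state.validate()

    V = timeline.volume

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        tan, tnn, no3, no, no2 = (max(v, 0.0) for v in y[:5])
        q = timeline.Q_at(t)
        fox = timeline.f_ox_at(t)
        tan_in = timeline.TAN_in_at(t)
        do = timeline.DO_at(t)
        state = SolutionState(
            TAN=tan,
            TNN=tnn,
            NO3_N=no3,
            NO_aq=no,
            NO2g_aq=no2,
            DO=max(do, 0.0),
            pH=timeline.pH_at(t),
            temperature=timeline.temperature_at(t),
            ionic_strength=ionic_strength_from_conductivity(
                max(timeline.conductivity_at(t), 0.0), ec_to_ionic_strength
            ),
        )
        aerated = do > AERATION_DO_THRESHOLD
        chem_d = species_derivatives(state, chem, gas, aerated, speciation)
        dil = q / V
        d = np.empty(10)
        d[0] = dil * ((1.0 - fox) * tan_in - tan) + chem_d["TAN"]
        d[1] = dil * (fox * tan_in - tnn) + chem_d["TNN"]
        d[2] = -dil * no3 + chem_d["NO3_N"]
        d[3] = -dil * no + chem_d["NO_aq"]
        d[4] = -dil * no2 + chem_d["NO2g_aq"]
        d[5] = V * chem_d["strip_NO"]
        d[6] = V * chem_d["strip_NO2"]
        d[7] = V * chem_d["N2_cum"]
        d[8] = q * tan_in
        d[9] = q * (tan + tnn + no3 + no + no2)
        return d

    y0 = np.zeros(10)
    for i, name in enumerate(_SPECIES):
        y0[i] = getattr(initial_state, name)

    if t_eval is None:
        t_eval = timeline.time
    t_span = (float(timeline.time[0]), float(timeline.time[-1]))
    max_step = max(float(np.median(np.diff(timeline.time))), 1e-6)
    sol = solve_ivp(
        rhs, t_span, y0, method=method, rtol=rtol, atol=atol, t_eval=t_eval, max_step=max_step
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else t_span[0]
        raise RuntimeError(f"CSTR integration failed at t={last_t:.6g} d: {sol.message}")

    y = np.clip(sol.y, 0.0, None)
    return SimulationResult(
        time=sol.t,
        species={name: y[i] for i, name in enumerate(_SPECIES)},
        stripped_NO=y[5],
        stripped_NO2=y[6],
        n2_produced=y[7],
        influent_N=y[8],
        effluent_N=y[9],
        volume=V,
        diagnostics={"nfev": sol.nfev, "status": sol.status, "method": method},
    )


def fit_to_measurements(
    result: SimulationResult,
    measured_TNN: np.ndarray,
    measured_NO3: np.ndarray,
    measured_time: np.ndarray | None = None,
) -> dict[str, FitReport]:
    """Nash-Sutcliffe efficiency of the simulated TNN and nitrate series.

    If the measurements live on their own grid, the simulation is linearly
    interpolated onto it (logged).  Constant measured series make E
    undefined and raise.
    """
    if measured_time is None:
        sim_tnn = result.TNN
        sim_no3 = result.NO3_N
    else:
        logger.info("interpolating simulation onto the measurement grid (linear)")
        sim_tnn = np.interp(measured_time, result.time, result.TNN)
        sim_no3 = np.interp(measured_time, result.time, result.NO3_N)
    return {
        "TNN": fit_report(measured_TNN, sim_tnn),
        "NO3": fit_report(measured_NO3, sim_no3),
    }
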