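"""Derived process quantities for partial nitritation of urine.

Small, sharp-edged functions: Nash-Sutcliffe model efficiency for judging
simulated against measured series, the nitrite accumulation ratio (NAR),
nitrogen-loss fractions from a whole-run balance, chemostat identities
(HRT = SRT without sludge retention, hence net growth rate = 1/SRT at
washout), the alkalinity-limited conversion fraction, and volumetric
ammonia / nitrite oxidation rates reconstructed from concentration series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitReport",
    "NitrogenBalance",
    "model_efficiency",
    "fit_report",
    "nitrite_accumulation_ratio",
    "net_growth_rate_from_srt",
    "alkalinity_limited_fraction",
    "nitrogen_loss_fraction",
    "volumetric_rates",
    "hydraulic_retention_time",
]


@dataclass(frozen=True)
class FitReport:
    """Nash-Sutcliffe efficiency with its residuals.

    ``E <= 1`` always; ``E == 1`` iff every residual is zero; ``E == 0``
    means the model does no better than the measured mean.
    """

    E: float
    residuals: np.ndarray
    n: int


@dataclass(frozen=True)
class NitrogenBalance:
    """Whole-run nitrogen ledger in mg-N.

    ``gaseous`` is the directly accounted gas-phase loss when available;
    the *dissolved* loss implied by the balance is
    ``influent - effluent - storage_change`` and the two agree for a closed
    simulation.
    """

    influent: float
    effluent: float
    storage_change: float
    gaseous: float = float("nan")

    def implied_loss(self) -> float:
        return self.influent - self.effluent - self.storage_change


def model_efficiency(measured, simulated) -> float:
    """Nash-Sutcliffe model efficiency E.

    E = 1 - sum((y_m - y_s)^2) / sum((y_m - mean(y_m))^2)

    The measured series must be non-constant (otherwise the normalising
    variance vanishes and E is undefined).
    """
    return fit_report(measured, simulated).E


def fit_report(measured, simulated) -> FitReport:
    """Like :func:`model_efficiency` but keeps residuals and n."""
    y_m = np.asarray(measured, dtype=float)
    y_s = np.asarray(simulated, dtype=float)
    if y_m.shape != y_s.shape:
        raise ValueError(f"length mismatch: measured {y_m.shape} vs simulated {y_s.shape}")
    if y_m.size < 2:
        raise ValueError("need at least two observations")
    denom = float(np.sum((y_m - y_m.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("model efficiency undefined: measured series is constant")
    residuals = y_m - y_s
    e = 1.0 - float(np.sum(residuals**2)) / denom
    return FitReport(E=e, residuals=residuals, n=y_m.size)


def nitrite_accumulation_ratio(TNN_eff: float, NO3_eff: float) -> float:
    """NAR in percent: the share of oxidized N remaining as nitrite.

    NAR = 100 * TNN / (TNN + NO3).
    """
    if TNN_eff < 0 or NO3_eff < 0:
        raise ValueError("effluent concentrations must be non-negative")
    total = TNN_eff + NO3_eff
    if total == 0:
        raise ValueError("NAR undefined: no oxidized nitrogen present")
    return 100.0 * TNN_eff / total


def net_growth_rate_from_srt(SRT: float) -> float:
    """Maximum net growth rate (1/d) sustained at solids retention time SRT.

    In a chemostat without sludge retention SRT equals HRT, and organisms
    persisting at the minimum observed SRT must grow at least at the
    washout rate mu = 1/SRT.
    """
    if SRT <= 0:
        raise ValueError("SRT must be positive")
    return 1.0 / SRT


def alkalinity_limited_fraction(alkalinity: float, TAN_molar: float) -> float:
    """Fraction of TAN that can be nitritated before alkalinity runs out.

    Ammonia oxidation to nitrite releases two proton equivalents per mol N,
    so f = min(1, ALK / (2 TAN)); at the 1:1 molar alkalinity:TAN ratio of
    stored urine this caps conversion near 50%.
    """
    if alkalinity < 0:
        raise ValueError("alkalinity must be non-negative")
    if TAN_molar <= 0:
        raise ValueError("TAN must be positive")
    return min(1.0, alkalinity / (2.0 * TAN_molar))


def nitrogen_loss_fraction(balance: NitrogenBalance) -> float:
    """Percent of influent nitrogen not recovered dissolved in the effluent.

    100 * (influent - effluent - storage_change) / influent.
    """
    if balance.influent <= 0:
        raise ValueError("influent load must be positive")
    return 100.0 * balance.implied_loss() / balance.influent


def hydraulic_retention_time(volume: float, Q: float) -> float:
    """HRT = V / Q in days."""
    if Q <= 0:
        raise ValueError("flow rate must be positive for a finite HRT")
    if volume <= 0:
        raise ValueError("volume must be positive")
    return volume / Q


def _gradient(series: np.ndarray, time: np.ndarray, smooth: int | None) -> np.ndarray:
    if smooth is not None and smooth > 1:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        padded = np.pad(series, pad, mode="edge")
        series = np.convolve(padded, kernel, mode="same")[pad : pad + len(time)]
    return np.gradient(series, time)


def volumetric_rates(
    time: np.ndarray,
    Q: np.ndarray,
    volume: float,
    TAN_in: np.ndarray,
    TAN: np.ndarray,
    NO3: np.ndarray,
    smooth: int | None = None,
) -> dict[str, np.ndarray]:
    """Ammonia and nitrite oxidation rates (AOR, NOR) in mg-N/(L d).

    Reconstructed from the reactor mass balance with the accumulation term
    included (centered finite differences, optional moving-average
    smoothing for noisy series):

        AOR = (Q/V) (TAN_in - TAN) - dTAN/dt
        NOR = (Q/V) NO3 + dNO3/dt          (nitrate-free influent)

    At steady state these reduce to the familiar load-difference forms.
    """
    arrays = [np.asarray(a, dtype=float) for a in (time, Q, TAN_in, TAN, NO3)]
    time, Q, TAN_in, TAN, NO3 = arrays
    n = time.shape
    if any(a.shape != n for a in (Q, TAN_in, TAN, NO3)):
        raise ValueError("all series must share the time grid")
    if volume <= 0:
        raise ValueError("volume must be positive")
    dil = Q / volume
    aor = dil * (TAN_in - TAN) - _gradient(TAN, time, smooth)
    nor = dil * NO3 + _gradient(NO3, time, smooth)
    return {"AOR": aor, "NOR": nor}
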