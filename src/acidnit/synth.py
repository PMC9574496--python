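"""Synthetic reactor-operation timelines.

Generates :class:`~acidnit.reactor.OperationTimeline` objects with the
statistical structure of an acidic urine-nitritation CSTR: urine-strength
influent (TAN up to ~3500 mg-N/L, stepping when the feed tank is changed),
pH held in a narrow acidic band (default 4.9-5.0) by pulsing the alkaline
influent with an on-off controller, DO cycling in its control band
(default 4-6 mg/L), temperature near 25 degC, and conductivity tracking the
influent strength.

The pH trajectory during control is emulated phenomenologically — linear
acidification while the pump is off, linear recovery while it feeds — so
the generator stays independent of the chemistry model it is used to test.
Four disturbance classes can be injected on top: influent stop (pH sags
toward a floor of 4), aeration stop (DO to zero for 3-15 h), uncontrolled
over-pumping (pH rises toward 8.5), and overheating (temperature toward
33 degC).

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .reactor import OperationTimeline

__all__ = [
    "ScenarioConfig",
    "DisturbanceSpec",
    "generate_timeline",
    "inject_disturbance",
    "add_measurement_noise",
]


class ScenarioConfig(BaseModel):
    """Scenario description for the timeline generator.

    Ranges are (low, high) and must be ordered; per-channel measurement
    noise is additive Gaussian, applied after the clean signals are built
    and clipped at physical bounds.
    """

    duration: float = Field(default=100.0, gt=0, description="scenario length, d")
    dt: float = Field(default=0.01, gt=0, description="grid resolution, d")
    volume: float = Field(default=12.0, gt=0, description="reactor volume, L")
    tan_in_range: tuple[float, float] = (1000.0, 3500.0)
    ph_band: tuple[float, float] = (4.9, 5.0)
    do_band: tuple[float, float] = (4.0, 6.0)
    hrt_range: tuple[float, float] = (1.6, 10.0)
    ec_range: tuple[float, float] = (15.0, 35.0)
    temperature: float = Field(default=25.0, ge=0, le=45)
    f_ox: float = Field(default=0.5, ge=0, le=1)
    tan_mode: Literal["step", "drift"] = "step"
    tan_step_interval: float = Field(default=10.0, gt=0, description="feed-tank change interval, d")
    ph_fall_rate: float = Field(default=0.5, gt=0, description="acidification rate, pH/d")
    ph_rise_rate: float = Field(default=2.0, gt=0, description="recovery rate while feeding, pH/d")
    do_period: float = Field(default=0.02, gt=0, description="DO on-off cycle period, d")
    noise_sigma: dict[str, float] = Field(
        default_factory=lambda: {"T_C": 0.05, "EC_mS_cm": 0.2}
    )
    seed: int = 0

    @model_validator(mode="after")
    def _ordered_ranges(self) -> "ScenarioConfig":
        for name in ("tan_in_range", "ph_band", "do_band", "hrt_range", "ec_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered (low, high), got ({lo}, {hi})")
        if any(s < 0 for s in self.noise_sigma.values()):
            raise ValueError("noise sigmas must be non-negative")
        return self


class DisturbanceSpec(BaseModel):
    """One operational disturbance.

    ``duration`` is in days; for ``aeration_stop`` it may be omitted, in
    which case it is drawn uniformly from 3-15 hours (seeded).  Magnitude
    defaults follow the printed disturbance catalogue: pH floor 4 for
    influent stops, pH ceiling 8.5 for over-pumping, 33 degC overheating.
    """

    kind: Literal["influent_stop", "aeration_stop", "overpumping", "overheating"]
    start: float = Field(ge=0)
    duration: Optional[float] = Field(default=None, gt=0)
    ph_floor: float = 4.0
    ph_ceiling: float = 8.5
    temperature_peak: float = 33.0
    relax_tau: float = Field(default=0.3, gt=0, description="relaxation time constant, d")
    pump_turnovers_per_day: float = Field(
        default=2.0, gt=0, description="over-pumping rate in reactor volumes per day"
    )
    seed: int = 0

    def resolved_duration(self) -> float:
        if self.duration is not None:
            return self.duration
        if self.kind == "aeration_stop":
            rng = np.random.default_rng(self.seed)
            return float(rng.uniform(3.0, 15.0)) / 24.0
        raise ValueError(f"duration required for disturbance kind {self.kind!r}")


def generate_timeline(config: ScenarioConfig) -> OperationTimeline:
    """Deterministically realize one operation timeline from a scenario.

    The feed pump and pH are co-simulated as a two-state on-off controller:
    pH falls at ``ph_fall_rate`` while the pump is off and rises at
    ``ph_rise_rate`` while it feeds; the pump magnitude is sized so that the
    duty cycle delivers the target HRT on average.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration / config.dt)) + 1
    time = np.arange(n) * config.dt

    # influent strength: steps at tank changes, or a bounded random walk
    lo, hi = config.tan_in_range
    if config.tan_mode == "step":
        n_steps = int(np.ceil(config.duration / config.tan_step_interval)) + 1
        levels = rng.uniform(lo, hi, size=n_steps)
        idx = np.minimum((time / config.tan_step_interval).astype(int), n_steps - 1)
        tan_in = levels[idx]
    else:
        steps = rng.normal(0.0, (hi - lo) * 0.01, size=n)
        tan_in = np.clip(np.cumsum(steps) + rng.uniform(lo, hi), lo, hi)

    # pH / pump on-off controller
    ph_lo, ph_hi = config.ph_band
    hrt = float(rng.uniform(*config.hrt_range))
    q_mean = config.volume / hrt
    duty = config.ph_fall_rate / (config.ph_fall_rate + config.ph_rise_rate)
    q_on = q_mean / duty
    ph = np.empty(n)
    q = np.empty(n)
    ph[0] = float(rng.uniform(ph_lo, ph_hi))
    pumping = False
    for i in range(1, n):
        if pumping:
            ph[i] = ph[i - 1] + config.ph_rise_rate * config.dt
            if ph[i] >= ph_hi:
                ph[i] = ph_hi
                pumping = False
        else:
            ph[i] = ph[i - 1] - config.ph_fall_rate * config.dt
            if ph[i] <= ph_lo:
                ph[i] = ph_lo
                pumping = True
        q[i - 1] = q_on if pumping else 0.0
    q[-1] = q[-2]

    # DO on-off cycling: triangle wave spanning the control band
    do_lo, do_hi = config.do_band
    phase = (time / config.do_period) % 1.0
    tri = np.where(phase < 0.5, 2.0 * phase, 2.0 * (1.0 - phase))
    do = do_lo + (do_hi - do_lo) * tri

    temperature = np.full(n, config.temperature)

    # conductivity tracks influent strength across its configured range
    ec_lo, ec_hi = config.ec_range
    span = hi - lo
    frac = (tan_in - lo) / span if span > 0 else np.zeros(n)
    ec = ec_lo + (ec_hi - ec_lo) * frac

    noise = dict(config.noise_sigma)
    noise_seed = int(rng.integers(0, 2**31 - 1))
    channels = {
        "TAN_in_mgN_L": (tan_in, (0.0, None)),
        "pH": (ph, (0.0, 14.0)),
        "DO_mg_L": (do, (0.0, None)),
        "T_C": (temperature, (0.0, 45.0)),
        "EC_mS_cm": (ec, (0.0, None)),
    }
    noisy = {}
    for j, (name, (series, bounds)) in enumerate(channels.items()):
        sigma = noise.get(name, 0.0)
        noisy[name] = add_measurement_noise(
            series, sigma, seed=noise_seed + j, lower=bounds[0], upper=bounds[1]
        )

    return OperationTimeline(
        time=time,
        Q=q,
        TAN_in=noisy["TAN_in_mgN_L"],
        pH=noisy["pH"],
        DO=noisy["DO_mg_L"],
        temperature=noisy["T_C"],
        conductivity=noisy["EC_mS_cm"],
        volume=config.volume,
        f_ox=config.f_ox,
    )


def inject_disturbance(timeline: OperationTimeline, spec: DisturbanceSpec) -> OperationTimeline:
    """Return a copy of the timeline with one disturbance written in.

    The affected channels relax exponentially toward the disturbance
    magnitude inside the window and snap back to the controlled signal at
    its end (the controller re-engages).
    """
    duration = spec.resolved_duration()
    t0, t1 = spec.start, spec.start + duration
    time = timeline.time
    if t0 < time[0] or t1 > time[-1]:
        raise ValueError(
            f"disturbance window [{t0}, {t1}] outside timeline span [{time[0]}, {time[-1]}]"
        )
    mask = (time >= t0) & (time <= t1)
    if not mask.any():
        raise ValueError("disturbance window does not contain any grid point")

    Q = timeline.Q.copy()
    pH = timeline.pH.copy()
    DO = timeline.DO.copy()
    temperature = timeline.temperature.copy()
    tw = time[mask]
    i0 = int(np.argmax(mask))

    if spec.kind == "influent_stop":
        Q[mask] = 0.0
        start_ph = pH[i0]
        pH[mask] = spec.ph_floor + (start_ph - spec.ph_floor) * np.exp(-(tw - t0) / spec.relax_tau)
    elif spec.kind == "aeration_stop":
        DO[mask] = 0.0
    elif spec.kind == "overpumping":
        Q[mask] = spec.pump_turnovers_per_day * timeline.volume
        start_ph = pH[i0]
        pH[mask] = spec.ph_ceiling + (start_ph - spec.ph_ceiling) * np.exp(
            -(tw - t0) / spec.relax_tau
        )
    elif spec.kind == "overheating":
        start_t = temperature[i0]
        temperature[mask] = spec.temperature_peak + (start_t - spec.temperature_peak) * np.exp(
            -(tw - t0) / spec.relax_tau
        )

    return OperationTimeline(
        time=time.copy(),
        Q=Q,
        TAN_in=timeline.TAN_in.copy(),
        pH=pH,
        DO=DO,
        temperature=temperature,
        conductivity=timeline.conductivity.copy(),
        volume=timeline.volume,
        f_ox=timeline.f_ox if isinstance(timeline.f_ox, float) else timeline.f_ox.copy(),
    )


def add_measurement_noise(
    series: np.ndarray,
    sigma: float,
    seed: int,
    lower: float | None = None,
    upper: float | None = None,
) -> np.ndarray:
    """Additive Gaussian measurement noise, clipped at physical bounds."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    series = np.asarray(series, dtype=float)
    if sigma == 0:
        return series.copy()
    rng = np.random.default_rng(seed)
    noisy = series + rng.normal(0.0, sigma, size=series.shape)
    return np.clip(noisy, lower, upper)
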