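"""Synthetic hive-microclimate generator.

Produces temperature and CO2 series with the statistical structure the
analysis assumes: a ~24 h cosine with hive-specific phase, a slow multi-day
trend (linear drift plus AR(1) wander), Gaussian observation noise, an
optional 1 h ventilation artifact, amplitude decay across 3-d blocks under
cold-storage darkness, free-running period drift in darkness, and phase
re-entrainment to a 12L:12D light regime offset ~12 h from ambient.

The model is purely phenomenological — no bee clustering, metabolic heat or
gas exchange physics.  The signal is written as a 24 h carrier with a
time-varying phase offset,

    y(t) = mesor + trend(t) + A(t) * cos(2*pi*t/24 + phi(t)) + artifact + noise,

where a linearly drifting phi is exactly a cosine at the free-running
period, and exponential relaxation of phi toward a light-defined target
captures entrainment.  Each scenario carries one day of padding on both ends
so that the centered 48 h detrending window leaves the full experimental
span valid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import HiveSeries, ValidationError

TWO_PI = 2.0 * np.pi
HOURS_PER_DAY = 24.0


@dataclass
class RhythmParams:
    """Parameters of one hive's rhythm model (units of the target variable)."""

    mesor: float
    amplitude0: float
    phase: float  # radians, convention cos(2*pi*t/period + phase)
    period_h: float = 24.0
    amplitude_decay: float = 1.0  # multiplicative per 3-d block, in (0, 1]
    noise_sd: float = 0.0
    trend_slope_per_day: float = 0.0
    ar_coef: float = 0.0
    ar_sd: float = 0.0
    artifact_1h: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude0 < 0:
            raise ValidationError("amplitude0 must be >= 0")
        if not (0.0 < self.amplitude_decay <= 1.0):
            raise ValidationError("amplitude_decay must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class VariablePreset:
    """Per-variable scenario parameters (temperature degC or CO2 %)."""

    mesor: float
    amplitude0: float
    mu_phase: float  # mean ambient-entrained phase across hives
    amplitude_decay: float
    noise_sd: float
    free_running_period_h: float
    artifact_1h: float = 0.0
    trend_slope_per_day: float = 0.0
    ar_coef: float = 0.0
    ar_sd: float = 0.0


@dataclass
class Scenario:
    """One experiment design: hive count, sampling grid, regime schedule.

    ``segments`` is an ordered list of (regime, days) with regimes
    ``dark`` / ``light12`` / ``ambient``.  Days are counted from the
    experiment origin (day 1 = first experimental day); ``pad_days`` of
    ambient data are added before and after so the detrended series covers
    the whole schedule.
    """

    name: str
    n_hives: int
    sampling_interval: int  # minutes
    segments: list[tuple[str, float]]
    presets: dict[str, VariablePreset]
    lights_on_h: float = 18.0  # 6 PM local
    entrain_lag_days: float = 2.0
    entrain_rate_per_day: float = 1.0
    phase_dispersion_kappa: float = 8.0
    period_jitter_sd_h: float = 0.8
    pad_days: float = 1.0
    site: str = "CSU"
    start: str = "2023-12-08"
    seed: int = 0

    @property
    def duration_days(self) -> float:
        return float(sum(d for _, d in self.segments))


def _light_target_phase(preset: VariablePreset) -> float:
    # lights on 6 PM - 6 AM is ~12 h offset from ambient day: shift by pi
    return preset.mu_phase + np.pi


def _csu_variable_presets() -> dict[str, VariablePreset]:
    # Ambient-entrained peaks: in-hive temperature mid-afternoon (~15:00),
    # CO2 in the early morning hours (~03:00).  Free-running periods in
    # cold darkness: ~25.4 h (temperature), ~27.5 h (CO2).
    return {
        "temperature": VariablePreset(
            mesor=20.0,
            amplitude0=1.5,
            mu_phase=(-TWO_PI * 15.0 / 24.0) % TWO_PI,
            amplitude_decay=0.96,
            noise_sd=0.25,
            free_running_period_h=25.4,
            artifact_1h=0.03,
            trend_slope_per_day=-0.05,
            ar_coef=0.9,
            ar_sd=0.08,
        ),
        "co2": VariablePreset(
            mesor=1.5,
            amplitude0=0.5,
            mu_phase=(-TWO_PI * 3.0 / 24.0) % TWO_PI,
            amplitude_decay=1.0,
            noise_sd=0.08,
            free_running_period_h=27.5,
            artifact_1h=0.05,
            trend_slope_per_day=-0.01,
            ar_coef=0.9,
            ar_sd=0.03,
        ),
    }


def _outside_variable_presets() -> dict[str, VariablePreset]:
    return {
        "temperature": VariablePreset(
            mesor=34.0,
            amplitude0=1.0,
            mu_phase=(-TWO_PI * 15.0 / 24.0) % TWO_PI,
            amplitude_decay=1.0,
            noise_sd=0.3,
            free_running_period_h=24.0,
            trend_slope_per_day=0.0,
            ar_coef=0.9,
            ar_sd=0.1,
        ),
        "co2": VariablePreset(
            mesor=1.0,
            amplitude0=0.4,
            mu_phase=(-TWO_PI * 3.0 / 24.0) % TWO_PI,
            amplitude_decay=1.0,
            noise_sd=0.1,
            free_running_period_h=24.0,
            trend_slope_per_day=0.0,
            ar_coef=0.9,
            ar_sd=0.04,
        ),
    }


def scenario_presets() -> dict[str, Scenario]:
    """The four built-in experiment emulations."""
    return {
        # three weeks in cold darkness, 30-min sampling, no light regime
        "fall_csu": Scenario(
            name="fall_csu",
            n_hives=8,
            sampling_interval=30,
            segments=[("dark", 21.0)],
            presets=_csu_variable_presets(),
            site="CSU",
            start="2020-10-01",
        ),
        # control group outside in ambient conditions
        "fall_outside": Scenario(
            name="fall_outside",
            n_hives=8,
            sampling_interval=30,
            segments=[("ambient", 21.0)],
            presets=_outside_variable_presets(),
            site="outside",
            start="2020-10-01",
        ),
        # 6 d darkness, 12 d reversed 12L:12D, then back outside
        "summer_csu": Scenario(
            name="summer_csu",
            n_hives=16,
            sampling_interval=5,
            segments=[("dark", 6.0), ("light12", 12.0), ("ambient", 6.0)],
            presets=_csu_variable_presets(),
            site="CSU",
            start="2023-06-22",
        ),
        # 12 d darkness, 33 d reversed 12L:12D, 12 d back outside
        "winter_csu": Scenario(
            name="winter_csu",
            n_hives=16,
            sampling_interval=5,
            segments=[("dark", 12.0), ("light12", 33.0), ("ambient", 12.0)],
            presets=_csu_variable_presets(),
            site="CSU",
            start="2023-12-08",
        ),
    }


def get_scenario(name: str, **overrides) -> Scenario:
    presets = scenario_presets()
    if name not in presets:
        raise ValidationError(
            f"unknown scenario {name!r}; available: {sorted(presets)}"
        )
    return replace(presets[name], **overrides)


# ---------------------------------------------------------------------------
# low-level generator


def gen_hive(
    params: RhythmParams,
    duration_days: float,
    sampling_interval: int,
    seed: int,
    hive_id: str = "hive",
    variable: str = "temperature",
    site: str = "CSU",
    experiment: str = "synthetic",
    start: str = "2023-12-08",
) -> HiveSeries:
    """One hive's series under a fixed phase (no entrainment dynamics).

    The amplitude steps down by ``amplitude_decay`` at every 3-d boundary;
    trend is a linear drift plus a stationary AR(1) component; noise is iid
    Gaussian.  Deterministic for a fixed seed.
    """
    if duration_days < 3:
        raise ValidationError("duration must be >= 3 d")
    rng = np.random.default_rng(seed)
    n = int(round(duration_days * HOURS_PER_DAY * 60.0 / sampling_interval))
    t_h = np.arange(n) * sampling_interval / 60.0
    block = np.floor(t_h / 72.0)
    amp = params.amplitude0 * params.amplitude_decay**block
    values = (
        params.mesor
        + params.trend_slope_per_day * t_h / HOURS_PER_DAY
        + _ar1(rng, n, params.ar_coef, params.ar_sd)
        + amp * np.cos(TWO_PI * t_h / params.period_h + params.phase)
        + params.artifact_1h * np.cos(TWO_PI * t_h)
        + rng.normal(0.0, params.noise_sd, size=n)
    )
    if variable == "co2":
        values = np.maximum(values, 0.0)
    ts = pd.date_range(pd.Timestamp(start), periods=n, freq=pd.Timedelta(minutes=sampling_interval))
    return HiveSeries(
        hive_id=hive_id,
        variable=variable,
        site=site,
        experiment=experiment,
        timestamps=ts,
        values=values,
        sampling_interval=sampling_interval,
    )


def _ar1(rng: np.random.Generator, n: int, coef: float, sd: float) -> np.ndarray:
    if sd == 0.0 or coef == 0.0:
        return np.zeros(n)
    from scipy.signal import lfilter

    e = rng.normal(0.0, sd, size=n)
    e[0] /= np.sqrt(1.0 - coef**2)  # stationary start
    return lfilter([1.0], [1.0, -coef], e)


def _wrap_pi(x):
    """Wrap to (-pi, pi] so relaxation takes the shorter arc."""
    return np.pi - np.mod(np.pi - np.asarray(x), TWO_PI)


def _phase_trajectory(
    t_h: np.ndarray,
    phi0: float,
    segments: list[tuple[str, float]],
    pad_days: float,
    free_period_h: float,
    mu_ambient: float,
    light_target: float,
    lag_days: float,
    rate_per_day: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase offset phi(t) and its derivative (rad/day).

    ``t_h`` is measured from the padded series start; the schedule proper
    begins after ``pad_days``.  In darkness the phase drifts linearly at the
    rate implied by the free-running period; under the light regime it
    relaxes exponentially toward the light-defined target after a lag; in
    ambient conditions it relaxes toward the ambient-entrained phase with no
    lag.
    """
    drift = TWO_PI * (HOURS_PER_DAY / free_period_h - 1.0)  # rad/day
    phi = np.empty_like(t_h)
    dphi = np.empty_like(t_h)
    bounds = [("ambient", pad_days)] + list(segments) + [("ambient", pad_days)]
    t_days = t_h / HOURS_PER_DAY
    seg_start = 0.0
    phi_enter = phi0
    for regime, days in bounds:
        seg_end = seg_start + days
        m = (t_days >= seg_start - 1e-12) & (t_days < seg_end - 1e-12)
        tau = t_days[m] - seg_start
        if regime == "dark":
            phi[m] = phi_enter + drift * tau
            dphi[m] = drift
            phi_exit = phi_enter + drift * days
        elif regime in ("light12", "ambient"):
            target = light_target if regime == "light12" else mu_ambient
            lag = lag_days if regime == "light12" else 0.0
            pre = tau < lag
            phi_seg = np.empty(len(tau))
            dphi_seg = np.empty(len(tau))
            # before the lag the clock keeps free-running
            phi_seg[pre] = phi_enter + drift * tau[pre]
            dphi_seg[pre] = drift
            phi_lag = phi_enter + drift * min(lag, days)
            delta0 = _wrap_pi(phi_lag - target)
            decay = np.exp(-rate_per_day * (tau[~pre] - lag))
            phi_seg[~pre] = target + delta0 * decay
            dphi_seg[~pre] = -rate_per_day * delta0 * decay
            phi[m] = phi_seg
            dphi[m] = dphi_seg
            if days <= lag:
                phi_exit = phi_enter + drift * days
            else:
                phi_exit = target + delta0 * np.exp(-rate_per_day * (days - lag))
        else:
            raise ValidationError(f"unknown regime {regime!r}")
        phi_enter = phi_exit
        seg_start = seg_end
    return phi, dphi


def _regime_at(day, segments: list[tuple[str, float]]):
    """Regime label at experiment day(s); past the schedule means ambient."""
    edges = np.cumsum([d for _, d in segments])
    labels = np.array([r for r, _ in segments] + ["ambient"], dtype=object)
    idx = np.searchsorted(edges, np.asarray(day), side="right")
    out = labels[idx]
    return out if np.ndim(day) else str(out)


def gen_experiment(
    scenario: Scenario, variables: tuple[str, ...] = ("temperature", "co2")
) -> tuple[list[HiveSeries], pd.DataFrame]:
    """Simulate all hives of a scenario, with ground truth for recovery tests.

    Returns ``(series, truth)`` where ``series`` holds one HiveSeries per
    hive and variable, and ``truth`` has one row per hive x variable x 3-d
    block with the programmed phase (24 h-carrier offset at block midpoint),
    instantaneous period, amplitude and regime.  Hive phases are drawn von
    Mises around the preset mean with concentration
    ``phase_dispersion_kappa`` (kappa above 1e6 means identical phases);
    per-hive randomness uses substreams seed + hive index.
    """
    total_days = scenario.duration_days + 2 * scenario.pad_days
    n = int(round(total_days * HOURS_PER_DAY * 60.0 / scenario.sampling_interval))
    t_h = np.arange(n) * scenario.sampling_interval / 60.0
    start_ts = pd.Timestamp(scenario.start) - pd.Timedelta(days=scenario.pad_days)
    ts = pd.date_range(start_ts, periods=n, freq=pd.Timedelta(minutes=scenario.sampling_interval))

    # 3-d truth blocks over the experiment proper (not the pads)
    n_blocks = int(np.floor(scenario.duration_days / 3.0))

    series: list[HiveSeries] = []
    truth_rows = []
    for h in range(scenario.n_hives):
        hive_id = f"hive{h + 1:02d}"
        rng = np.random.default_rng(scenario.seed + h)
        for variable in variables:
            preset = scenario.presets[variable]
            if scenario.phase_dispersion_kappa > 1e6:
                phi0 = preset.mu_phase
            else:
                phi0 = float(rng.vonmises(preset.mu_phase, scenario.phase_dispersion_kappa))
            free_period = preset.free_running_period_h
            if scenario.period_jitter_sd_h > 0 and free_period != HOURS_PER_DAY:
                free_period += float(rng.normal(0.0, scenario.period_jitter_sd_h))
            phi, dphi = _phase_trajectory(
                t_h,
                phi0,
                scenario.segments,
                scenario.pad_days,
                free_period,
                preset.mu_phase,
                _light_target_phase(preset),
                scenario.entrain_lag_days,
                scenario.entrain_rate_per_day,
            )
            # amplitude decays across 3-d blocks while in the CSU; restored outside
            day = t_h / HOURS_PER_DAY - scenario.pad_days
            regimes = _regime_at(np.maximum(day, 0.0), scenario.segments)
            in_csu = (regimes != "ambient") & (day >= 0)
            block = np.floor(np.maximum(day, 0.0) / 3.0)
            amp = np.where(
                in_csu,
                preset.amplitude0 * preset.amplitude_decay**block,
                preset.amplitude0,
            )
            values = (
                preset.mesor
                + preset.trend_slope_per_day * day
                + _ar1(rng, n, preset.ar_coef, preset.ar_sd)
                + amp * np.cos(TWO_PI * t_h / HOURS_PER_DAY + phi)
                + preset.artifact_1h * np.cos(TWO_PI * t_h) * in_csu
                + (rng.normal(0.0, preset.noise_sd, size=n) if preset.noise_sd > 0 else 0.0)
            )
            if variable == "co2":
                values = np.maximum(values, 0.0)
            series.append(
                HiveSeries(
                    hive_id=hive_id,
                    variable=variable,
                    site=scenario.site,
                    experiment=scenario.name,
                    timestamps=ts,
                    values=values,
                    sampling_interval=scenario.sampling_interval,
                )
            )
            for b in range(n_blocks):
                mid_day = 3.0 * b + 1.5
                i_mid = int(np.argmin(np.abs(day - mid_day)))
                period_mid = 1.0 / (1.0 / HOURS_PER_DAY + dphi[i_mid] / (TWO_PI * HOURS_PER_DAY))
                truth_rows.append(
                    {
                        "hive_id": hive_id,
                        "variable": variable,
                        "subset": b + 1,
                        "day_mid": mid_day,
                        "regime": _regime_at(mid_day, scenario.segments),
                        "phase_rad": float(np.mod(phi[i_mid], TWO_PI)),
                        "phase_drift_rad_per_day": float(dphi[i_mid]),
                        "period_h": float(period_mid),
                        "amplitude": float(amp[i_mid]),
                        "mesor": preset.mesor,
                    }
                )
    return series, pd.DataFrame(truth_rows)


def config_hash(obj) -> str:
    """Stable short hash of a plain-data config structure."""

    def _canon(x):
        if isinstance(x, dict):
            return "{" + ",".join(f"{k}:{_canon(v)}" for k, v in sorted(x.items())) + "}"
        if isinstance(x, (list, tuple)):
            return "[" + ",".join(_canon(v) for v in x) + "]"
        return repr(x)

    return hashlib.sha256(_canon(obj).encode()).hexdigest()[:12]
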