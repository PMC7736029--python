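"""Station-by-station model of an open-loop lab-scale spray dryer.

The dryer is instrumented at stations P1 (ambient intake) through P9
(exhaust behind the fine-particle filter). The model propagates a moist-air
state through the loop: heating to the inlet set point (P3), evaporative
cooling plus humidity gain across the atomisation zone (P4), lumped wall
heat loss down the drying column (P5) and further configured losses to the
collection point (P7) and exhaust sensor (P9). Humidity is constant from P4
onward — evaporation is taken as complete near the nozzle.

Also here: the quadratic relative-humidity response surface used to map the
feasible operating region, the operation limit band between passed and
failed runs, a Barth equilibrium-orbit cyclone cut size, the
moisture-compensated yield, and sensor-log parsing/segmentation utilities.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .material_state import GordonTaylorParams, SorptionIsotherm, ZoneLabel, classify_zone
from .psychrometry import (
    AIR_WATER,
    GasProperties,
    MoistAirState,
    evaporative_cooling,
    humidity_gain,
)

__all__ = [
    "DryerConfig",
    "StationState",
    "SensorLog",
    "ResponseSurface",
    "CycloneConfig",
    "YieldRecord",
    "Phase",
    "station_states",
    "fit_rh_response_surface",
    "operation_limit_band",
    "cyclone_cutoff",
    "process_yield",
    "parse_sensor_log",
    "segment_phases",
    "steady_state_extract",
    "filter_pressure_check",
]


class Phase(str, enum.Enum):
    """Run phases: dry-air, pure-solvent, production, shut-down."""

    DAP = "DAP"
    PSP = "PSP"
    PrP = "PrP"
    S = "S"


_PHASE_ORDER = [Phase.DAP, Phase.PSP, Phase.PrP, Phase.S]


@dataclass(frozen=True)
class DryerConfig:
    """Operating point and feed description of the dryer.

    ``feed_rate`` is volumetric (m^3/s); the sprayed water mass rate is
    ``feed_rate * feed_density * feed_water_fraction``.
    """

    dry_gas_mass_flow: float  # kg/s
    inlet_set_temperature: float  # K, heater set point at P3
    feed_rate: float  # m^3/s
    feed_water_fraction: float = 1.0  # mass fraction of water in the feed
    feed_solids_concentration: float = 30.0  # kg/m^3
    feed_density: float = 1000.0  # kg/m^3
    heat_loss_p4_p5: float = 25.0  # K, lumped drying-column wall loss
    heat_loss_p5_p7: float = 10.0  # K, cyclone/collection segment
    heat_loss_p7_p9: float = 5.0  # K, filter/exhaust segment
    ambient_state: MoistAirState = field(
        default_factory=lambda: MoistAirState.from_rh(295.15, 0.40)
    )
    gas: GasProperties = AIR_WATER

    def __post_init__(self) -> None:
        if self.dry_gas_mass_flow <= 0:
            raise ValueError("dry gas mass flow must be positive")
        if self.feed_rate < 0 or self.feed_solids_concentration < 0:
            raise ValueError("feed rate and solids concentration must be non-negative")
        if not 0.0 <= self.feed_water_fraction <= 1.0:
            raise ValueError("feed water fraction must lie in [0, 1]")

    @property
    def water_evaporation_rate(self) -> float:
        """Sprayed water mass rate, kg/s (evaporation assumed complete)."""
        return self.feed_rate * self.feed_density * self.feed_water_fraction


@dataclass(frozen=True)
class StationState:
    """Moist-air state at one instrumented station, with its zone label."""

    station_id: str
    state: MoistAirState
    zone: ZoneLabel | None = None
    supersaturated: bool = False


def station_states(
    config: DryerConfig,
    gt: GordonTaylorParams | None = None,
    isotherm: SorptionIsotherm | None = None,
    offset: float = 10.0,
) -> list[StationState]:
    """Propagate the gas state through stations P1, P3, P4, P5, P7, P9.

    P1 is ambient; P3 is heated to the set point at ambient humidity; P4
    applies evaporative cooling and the full humidity gain; P5/P7/P9 apply
    the configured lumped heat losses at constant humidity. Zone labels are
    attached when a material model is supplied. Supersaturation at a station
    is flagged on that station and the pipeline continues.
    """
    amb = config.ambient_state
    p = amb.total_pressure
    m_evap = config.water_evaporation_rate

    p3 = MoistAirState(config.inlet_set_temperature, amb.specific_humidity, p)
    dt_evap = evaporative_cooling(p3, config.gas, m_evap, config.dry_gas_mass_flow)
    p4_wet = humidity_gain(p3, m_evap, config.dry_gas_mass_flow)
    p4 = MoistAirState(p3.dry_bulb_temperature - dt_evap, p4_wet.specific_humidity, p)
    p5 = MoistAirState(
        p4.dry_bulb_temperature - config.heat_loss_p4_p5, p4.specific_humidity, p
    )
    p7 = MoistAirState(
        p5.dry_bulb_temperature - config.heat_loss_p5_p7, p5.specific_humidity, p
    )
    p9 = MoistAirState(
        p7.dry_bulb_temperature - config.heat_loss_p7_p9, p7.specific_humidity, p
    )

    out: list[StationState] = []
    for sid, st in [("P1", amb), ("P3", p3), ("P4", p4), ("P5", p5), ("P7", p7), ("P9", p9)]:
        zone = None
        if gt is not None and isotherm is not None and not st.supersaturated:
            zone = classify_zone(st, gt, isotherm, offset)
        out.append(
            StationState(sid, st, zone=zone, supersaturated=st.supersaturated)
        )
    return out


# ---------------------------------------------------------------------------
# RH response surface and operation limit band


@dataclass(frozen=True)
class ResponseSurface:
    """Quadratic response surface RH_P9(feed rate, inlet temperature).

    Coefficients order: 1, f, T, f^2, f*T, T^2. Failed (insufficient-drying)
    training points are stored but excluded from the fit.
    """

    coefficients: tuple[float, float, float, float, float, float]
    residual_sd: float
    n_passed: int
    excluded_points: tuple[tuple[float, float, float], ...] = ()

    def predict(self, feed_rate: float, inlet_temperature: float) -> float:
        f, t = feed_rate, inlet_temperature
        c = self.coefficients
        return c[0] + c[1] * f + c[2] * t + c[3] * f * f + c[4] * f * t + c[5] * t * t


def _design_matrix(f: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(f), f, t, f * f, f * t, t * t])


def fit_rh_response_surface(
    steady_points: Sequence[tuple[float, float, float, bool]],
) -> ResponseSurface:
    """OLS fit of the full two-variable quadratic to passed steady-state points.

    Each point is ``(feed_rate, inlet_T, RH_P9, passed)``; failed points are
    kept aside for the operation limit band. Requires at least 6 passed
    points of full rank.
    """
    passed = [(f, t, r) for f, t, r, ok in steady_points if ok]
    failed = [(f, t, r) for f, t, r, ok in steady_points if not ok]
    if len(passed) < 6:
        raise ValueError("need at least 6 passed points for the quadratic fit")
    f = np.asarray([p[0] for p in passed], dtype=float)
    t = np.asarray([p[1] for p in passed], dtype=float)
    r = np.asarray([p[2] for p in passed], dtype=float)
    x = _design_matrix(f, t)
    if np.linalg.matrix_rank(x) < 6:
        raise ValueError("rank-deficient design: points are collinear/degenerate")
    beta, _, _, _ = np.linalg.lstsq(x, r, rcond=None)
    resid = r - x @ beta
    dof = max(len(passed) - 6, 1)
    return ResponseSurface(
        coefficients=tuple(float(b) for b in beta),
        residual_sd=float(np.sqrt(resid @ resid / dof)),
        n_passed=len(passed),
        excluded_points=tuple(failed),
    )


def operation_limit_band(
    passed_rh: Sequence[float], failed_rh: Sequence[float]
) -> tuple[float, float]:
    """Operation limit band (rh_low, rh_high) on the exhaust RH axis.

    ``rh_low`` is the maximum RH among passed runs, ``rh_high`` the minimum
    among failed runs. An inverted band (overlap of the classes) is returned
    as-is with a warning rather than masked.
    """
    if len(passed_rh) == 0 or len(failed_rh) == 0:
        raise ValueError("need at least one passed and one failed run")
    rh_low = float(max(passed_rh))
    rh_high = float(min(failed_rh))
    if rh_low > rh_high:
        warnings.warn(
            f"passed/failed RH ranges overlap: max passed {rh_low} > "
            f"min failed {rh_high}",
            stacklevel=2,
        )
    return rh_low, rh_high


# ---------------------------------------------------------------------------
# Cyclone cut size


@dataclass(frozen=True)
class CycloneConfig:
    """Geometry and gas/particle properties for the cyclone cut-size model."""

    inlet_width: float  # m, tangential slot width b
    inlet_height: float  # m, slot height a
    body_diameter: float  # m
    vortex_finder_diameter: float  # m
    effective_length: float  # m, vortex finder lip to cone bottom
    gas_volumetric_flow: float  # m^3/s
    gas_viscosity: float = 1.85e-5  # Pa s
    particle_density: float = 1500.0  # kg/m^3
    gas_density: float = 1.2  # kg/m^3

    def __post_init__(self) -> None:
        for name in (
            "inlet_width",
            "inlet_height",
            "body_diameter",
            "vortex_finder_diameter",
            "effective_length",
            "gas_volumetric_flow",
            "gas_viscosity",
            "particle_density",
            "gas_density",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.particle_density <= self.gas_density:
            raise ValueError("particle density must exceed gas density")
        if self.inlet_width >= self.body_diameter / 2:
            raise ValueError("inlet width must be smaller than the body radius")


def cyclone_cutoff(config: CycloneConfig) -> float:
    """Barth equilibrium-orbit cut size d50 (m).

    A particle on the control surface at the vortex-finder radius is in
    equilibrium when Stokes drag from the inward radial flow balances the
    centrifugal force of the tangential motion:

    ``d50 = sqrt(9 mu Q / (pi H (rho_p - rho_g) v_theta^2))``

    with the tangential velocity at the control surface from a loss-free
    vortex spun up by the inlet jet,
    ``v_theta = v_in (D - b) / Dx``, ``v_in = Q / (a b)``.

    Scaling: d50 ~ Q^(-1/2) (v_theta ~ Q) and d50 ~ (rho_p - rho_g)^(-1/2).
    """
    q = config.gas_volumetric_flow
    v_in = q / (config.inlet_height * config.inlet_width)
    v_theta = v_in * (config.body_diameter - config.inlet_width) / config.vortex_finder_diameter
    d_rho = config.particle_density - config.gas_density
    return float(
        np.sqrt(
            9.0
            * config.gas_viscosity
            * q
            / (np.pi * config.effective_length * d_rho * v_theta**2)
        )
    )


# ---------------------------------------------------------------------------
# Yield


@dataclass(frozen=True)
class YieldRecord:
    product_mass: float  # kg
    rm180: float  # mass fraction of residual moisture at 180 degC
    feed_solute_concentration: float  # kg/m^3
    feed_volume_sprayed: float  # m^3
    yield_fraction: float

    @property
    def anomalous(self) -> bool:
        """Yield above 1 indicates an accounting anomaly, not a clamp."""
        return self.yield_fraction > 1.0


def process_yield(
    product_mass: float,
    rm180: float,
    feed_solute_concentration: float,
    feed_volume: float,
) -> YieldRecord:
    """Moisture-compensated process yield.

    ``yield = m_product (1 - RM180) / (c_feed V_feed)`` — the collected mass
    is discounted by its residual moisture so that yield counts dry solute
    only. Unit-invariant as long as mass and volume units are consistent
    between numerator and denominator.
    """
    if product_mass < 0 or rm180 < 0 or feed_solute_concentration < 0:
        raise ValueError("inputs must be non-negative")
    denom = feed_solute_concentration * feed_volume
    if denom <= 0:
        raise ValueError("feed solute mass (concentration * volume) must be positive")
    y = product_mass * (1.0 - rm180) / denom
    rec = YieldRecord(product_mass, rm180, feed_solute_concentration, feed_volume, y)
    return rec


# ---------------------------------------------------------------------------
# Sensor logs


#: required CSV columns for :func:`parse_sensor_log`
SENSOR_COLUMNS = {
    "time_s": "time_s",
    "T_P3_R_C": "T_P3_R_C",
    "T_P5_R_C": "T_P5_R_C",
    "T_P9_R_C": "T_P9_R_C",
    "RH_P9_R_pct": "RH_P9_R_pct",
    "p_P9_R_Pa": "p_P9_R_Pa",
    "FR_P11_R_mL_min": "FR_P11_R_mL_min",
}


@dataclass
class SensorLog:
    """Parsed process sensor log, SI units internally.

    ``data`` columns: time_s, T_P3_K, T_P5_K, T_P9_K, RH_P9 (fraction),
    p_P9_Pa, FR_P11_m3_s, and optionally phase.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.data["time_s"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if "phase" in self.data.columns:
            phases = [p for p in self.data["phase"].dropna().unique()]
            order = [p.value for p in _PHASE_ORDER]
            idx = [order.index(p) for p in phases if p in order]
            if idx != sorted(idx):
                raise ValueError("phases must appear in DAP, PSP, PrP, S order")


def parse_sensor_log(raw: pd.DataFrame) -> SensorLog:
    """Validate a raw sensor table and convert to internal SI units.

    Expects the external CSV contract columns (temperatures in Celsius, RH in
    percent, feed rate in mL/min); raises on missing channels or
    non-monotone time.
    """
    missing = [c for c in SENSOR_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"sensor log missing required channels: {missing}")
    t = raw["time_s"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing")
    df = pd.DataFrame(
        {
            "time_s": t,
            "T_P3_K": raw["T_P3_R_C"].to_numpy(dtype=float) + 273.15,
            "T_P5_K": raw["T_P5_R_C"].to_numpy(dtype=float) + 273.15,
            "T_P9_K": raw["T_P9_R_C"].to_numpy(dtype=float) + 273.15,
            "RH_P9": raw["RH_P9_R_pct"].to_numpy(dtype=float) / 100.0,
            "p_P9_Pa": raw["p_P9_R_Pa"].to_numpy(dtype=float),
            "FR_P11_m3_s": raw["FR_P11_R_mL_min"].to_numpy(dtype=float)
            * 1e-6
            / 60.0,
        }
    )
    if "phase" in raw.columns:
        df["phase"] = raw["phase"].to_numpy()
    return SensorLog(df)


def segment_phases(
    log: SensorLog,
    solution_switch_time: float | None = None,
    feed_threshold: float = 1e-9,
    persistence: int = 3,
) -> dict[Phase, tuple[float, float]]:
    """Phase boundaries from the feed-rate channel.

    DAP -> PSP at the first sustained (``persistence`` samples) non-zero feed;
    PrP -> S at the last sustained feed-off. The PSP -> PrP switch (solvent to
    solution) is indistinguishable in the sensors and must be supplied as
    ``solution_switch_time``; without it, the whole feeding interval is
    labelled PSP. Returns ``{phase: (t_start, t_end)}`` over present phases.
    """
    df = log.data
    t = df["time_s"].to_numpy()
    fr = df["FR_P11_m3_s"].to_numpy()
    n = len(t)
    on = fr > feed_threshold

    def first_sustained(mask: np.ndarray) -> int | None:
        run = 0
        for i, m in enumerate(mask):
            run = run + 1 if m else 0
            if run >= persistence:
                return i - persistence + 1
        return None

    i_on = first_sustained(on)
    if i_on is None:
        return {Phase.DAP: (float(t[0]), float(t[-1]))}
    # first sustained feed-off after feeding started marks shut-down
    i_off = first_sustained(~on[i_on:])
    if i_off is not None:
        i_off += i_on

    bounds: dict[Phase, tuple[float, float]] = {}
    if i_on > 0:
        bounds[Phase.DAP] = (float(t[0]), float(t[i_on - 1]))
    feed_end = i_off - 1 if i_off is not None else n - 1
    if solution_switch_time is not None and solution_switch_time < t[feed_end]:
        i_sw = int(np.searchsorted(t, solution_switch_time))
        bounds[Phase.PSP] = (float(t[i_on]), float(t[max(i_sw - 1, i_on)]))
        bounds[Phase.PrP] = (float(t[i_sw]), float(t[feed_end]))
    else:
        bounds[Phase.PSP] = (float(t[i_on]), float(t[feed_end]))
    if i_off is not None and i_off < n:
        bounds[Phase.S] = (float(t[i_off]), float(t[-1]))
    return bounds


def steady_state_extract(
    log: SensorLog,
    window: tuple[float, float],
    sd_rh_max: float = 0.01,
    sd_t_max: float = 1.0,
) -> pd.DataFrame:
    """Per-channel mean and sd over a time window, with a stationarity check.

    The window is stationary when sd(RH) < ``sd_rh_max`` (fraction) and every
    temperature sd < ``sd_t_max`` K; the result carries a ``stationary``
    column per channel.
    """
    t0, t1 = window
    df = log.data
    sel = df[(df["time_s"] >= t0) & (df["time_s"] <= t1)]
    if sel.empty:
        raise ValueError("empty steady-state window")
    rows = []
    for col in ("T_P3_K", "T_P5_K", "T_P9_K", "RH_P9", "p_P9_Pa", "FR_P11_m3_s"):
        mean = float(sel[col].mean())
        sd = float(sel[col].std(ddof=0))
        if col == "RH_P9":
            stationary = sd < sd_rh_max
        elif col.startswith("T_"):
            stationary = sd < sd_t_max
        else:
            stationary = True
        rows.append({"channel": col, "mean": mean, "sd": sd, "stationary": stationary})
    return pd.DataFrame(rows).set_index("channel")


def filter_pressure_check(
    log: SensorLog,
    baseline_window: tuple[float, float],
    threshold: float = 0.05,
) -> tuple[float, bool]:
    """Maximum relative trans-filter pressure change, and pass/fail.

    ``dp(t) = p(t=0) - p(t)`` with the baseline pressure averaged over
    ``baseline_window``; returns ``(max |dp| / p_baseline, max < threshold)``.
    A creeping pressure drop signals fines loading the exhaust filter.
    """
    df = log.data
    t0, t1 = baseline_window
    base = df[(df["time_s"] >= t0) & (df["time_s"] <= t1)]["p_P9_Pa"]
    if base.empty:
        raise ValueError("empty baseline window")
    p0 = float(base.mean())
    dp_rel = float(np.max(np.abs(p0 - df["p_P9_Pa"].to_numpy()) / p0))
    return dp_rel, dp_rel < threshold
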