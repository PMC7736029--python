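"""Glass-transition and stickiness modelling of the amorphous solid.

The design-space machinery rests on three pieces:

* the Gordon-Taylor mixing rule, which predicts how residual moisture
  plasticises the amorphous solid and lowers its glass transition ``T_g``;
* a GAB sorption isotherm linking the local relative humidity of the drying
  gas to the equilibrium moisture content of the solid;
* the sticky-point criterion ``T_db = T_g + offset`` which, combined through
  the two models above, traces a stickiness curve on the psychrometric chart
  and partitions it into safe / transition / risk operating zones.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .psychrometry import MoistAirState, specific_humidity_from_rh

__all__ = [
    "GordonTaylorParams",
    "SorptionIsotherm",
    "StickinessCurve",
    "ZoneLabel",
    "TREHALOSE_WATER_GT",
    "TREHALOSE_GAB_PLACEHOLDER",
    "gordon_taylor_tg",
    "fit_gordon_taylor",
    "equilibrium_moisture",
    "fit_isotherm",
    "build_stickiness_curve",
    "classify_zone",
    "dihydrate_risk",
    "dry_basis_to_wet_fraction",
]


@dataclass(frozen=True)
class GordonTaylorParams:
    """Gordon-Taylor parameters of a binary solid-water system.

    ``tg_solid`` and ``tg_water`` are the component glass transitions (K);
    ``k_constant`` is the dimensionless mixing constant K.
    """

    tg_solid: float
    tg_water: float
    k_constant: float
    k_stderr: float | None = None
    rss: float | None = None

    def __post_init__(self) -> None:
        if self.tg_solid <= self.tg_water:
            raise ValueError("tg_solid must exceed tg_water")
        if self.k_constant <= 0:
            raise ValueError("k_constant must be positive")


#: Trehalose-water system: component T_g values 389 K (dry trehalose) and
#: 136 K (water), mixing constant K = 6.04 fitted for this pair.
TREHALOSE_WATER_GT = GordonTaylorParams(tg_solid=389.0, tg_water=136.0, k_constant=6.04)


class ZoneLabel(str, enum.Enum):
    """Operating-zone classification on the psychrometric chart."""

    SAFE = "safe"  # T_db < T_g
    TRANSITION = "transition"  # T_g <= T_db <= T_g + offset
    RISK = "risk"  # T_db > T_g + offset


def gordon_taylor_tg(water_mass_fraction: float, params: GordonTaylorParams) -> float:
    """Glass transition (K) of the plasticised solid at wet-basis water fraction.

    ``T_g = (w_s T_g,s + K w_w T_g,w) / (w_s + K w_w)`` with ``w_s = 1 - w_w``.
    Strictly decreasing in the water fraction for K > 0 and bounded by the
    component values.
    """
    w_w = water_mass_fraction
    if not 0.0 <= w_w <= 1.0:
        raise ValueError(f"water mass fraction {w_w!r} outside [0, 1]")
    w_s = 1.0 - w_w
    k = params.k_constant
    return (w_s * params.tg_solid + k * w_w * params.tg_water) / (w_s + k * w_w)


def fit_gordon_taylor(
    pairs: Sequence[tuple[float, float]],
    tg_solid: float,
    tg_water: float,
) -> GordonTaylorParams:
    """Least-squares estimate of the Gordon-Taylor constant K.

    The component glass transitions are held fixed; only K is free. Returns
    the fitted parameters with the residual sum of squares and the standard
    error of K from the Gauss-Newton curvature.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 (water fraction, Tg) pairs")
    w = np.asarray([p[0] for p in pairs], dtype=float)
    tg = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any((w <= 0) | (w >= 1)):
        raise ValueError("water fractions must lie strictly inside (0, 1)")
    if np.ptp(w) == 0:
        raise ValueError("degenerate fit: all water fractions identical")

    def model(wf: np.ndarray, k: float) -> np.ndarray:
        ws = 1.0 - wf
        return (ws * tg_solid + k * wf * tg_water) / (ws + k * wf)

    popt, pcov = optimize.curve_fit(model, w, tg, p0=[5.0], maxfev=10000)
    k_hat = float(popt[0])
    resid = tg - model(w, k_hat)
    rss = float(resid @ resid)
    k_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.nan
    return GordonTaylorParams(
        tg_solid=tg_solid, tg_water=tg_water, k_constant=k_hat, k_stderr=k_se, rss=rss
    )


@dataclass(frozen=True)
class SorptionIsotherm:
    """GAB water sorption isotherm, dry basis.

    ``X(a_w) = Xm C K a_w / ((1 - K a_w)(1 - K a_w + C K a_w))`` where ``Xm``
    is the monolayer capacity (kg water / kg dry solid), ``C`` the energy
    constant and ``K`` (correction constant, distinct from the Gordon-Taylor
    K) tempers the multilayer term.
    """

    monolayer_capacity: float
    energy_constant_c: float
    correction_constant_k: float
    model_name: str = "GAB"
    rss: float | None = None

    def __post_init__(self) -> None:
        if self.monolayer_capacity <= 0:
            raise ValueError("monolayer capacity must be positive")
        if self.energy_constant_c <= 0:
            raise ValueError("energy constant C must be positive")
        if not 0.0 < self.correction_constant_k <= 1.05:
            raise ValueError("correction constant k must lie in (0, 1.05]")


#: Calibration placeholder for amorphous trehalose, to be refit from user
#: sorption data; values give a sorption curve of realistic shape and scale
#: (a few wt% uptake at mid humidity).
TREHALOSE_GAB_PLACEHOLDER = SorptionIsotherm(
    monolayer_capacity=0.065, energy_constant_c=10.0, correction_constant_k=0.89
)


def equilibrium_moisture(water_activity: float, isotherm: SorptionIsotherm) -> float:
    """Equilibrium moisture content X (kg water / kg dry solid) at water activity a_w."""
    a_w = water_activity
    if not 0.0 <= a_w < 1.0:
        raise ValueError(f"water activity {a_w!r} outside [0, 1)")
    xm = isotherm.monolayer_capacity
    c = isotherm.energy_constant_c
    k = isotherm.correction_constant_k
    ka = k * a_w
    return xm * c * ka / ((1.0 - ka) * (1.0 - ka + c * ka))


def fit_isotherm(pairs: Sequence[tuple[float, float]]) -> SorptionIsotherm:
    """Fit GAB parameters to (water activity, moisture content) data.

    Nonlinear least squares initialised from the classical quadratic-in-a_w
    transformation of the GAB form; needs at least 4 points spanning an a_w
    range of at least 0.3.
    """
    pairs = list(pairs)
    if len(pairs) < 4:
        raise ValueError("need at least 4 sorption points")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    x = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(a) < 0.3:
        raise ValueError("water-activity span must be at least 0.3 for a stable fit")
    if np.all(x <= 0):
        raise ValueError("all-zero moisture data cannot constrain the isotherm")

    def model(aw: np.ndarray, xm: float, c: float, k: float) -> np.ndarray:
        ka = k * aw
        return xm * c * ka / ((1.0 - ka) * (1.0 - ka + c * ka))

    popt, _ = optimize.curve_fit(
        model,
        a,
        x,
        p0=[max(x.max() / 3.0, 1e-4), 10.0, 0.8],
        bounds=([1e-8, 1e-6, 1e-6], [np.inf, np.inf, 1.05]),
        maxfev=20000,
    )
    resid = x - model(a, *popt)
    return SorptionIsotherm(
        monolayer_capacity=float(popt[0]),
        energy_constant_c=float(popt[1]),
        correction_constant_k=float(popt[2]),
        rss=float(resid @ resid),
    )


def dry_basis_to_wet_fraction(moisture_dry_basis: float) -> float:
    """Convert dry-basis moisture X (kg/kg solid) to wet-basis mass fraction.

    ``w_w = X / (1 + X)`` — the Gordon-Taylor rule takes wet-basis fractions
    while sorption isotherms are conventionally dry-basis.
    """
    if moisture_dry_basis < 0:
        raise ValueError("moisture content must be non-negative")
    return moisture_dry_basis / (1.0 + moisture_dry_basis)


def _tg_at_rh(rh: float, gt: GordonTaylorParams, isotherm: SorptionIsotherm) -> float:
    """Material T_g when equilibrated against gas at relative humidity ``rh``."""
    x = equilibrium_moisture(rh, isotherm)
    return gordon_taylor_tg(dry_basis_to_wet_fraction(x), gt)


@dataclass(frozen=True)
class StickinessCurve:
    """Locus of sticky gas states, ``T_db = T_g(equilibrium moisture) + offset``.

    ``points`` are (dry-bulb temperature K, specific humidity kg/kg) pairs,
    strictly ordered in temperature, ready to overlay on a psychrometric
    chart.
    """

    offset: float
    points: tuple[tuple[float, float], ...]
    relative_humidities: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        temps = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("stickiness-curve points must be strictly ordered in T")


def build_stickiness_curve(
    gt: GordonTaylorParams,
    isotherm: SorptionIsotherm,
    offset: float,
    pressure: float,
    temperature_grid: Sequence[float],
) -> StickinessCurve:
    """Solve the sticky-point condition for RH at each grid temperature.

    At each dry-bulb temperature the sticky relative humidity satisfies
    ``T_g(w(X(RH))) + offset = T_db``. The left side is strictly decreasing
    in RH (more moisture, lower T_g), so bisection on RH in (1e-6, 0.999) is
    guaranteed to converge; grid points with no root in that bracket are
    omitted with a warning.
    """
    points: list[tuple[float, float]] = []
    rhs: list[float] = []
    lo, hi = 1e-6, 0.999
    for t_db in temperature_grid:

        def residual(rh: float, t_db: float = t_db) -> float:
            return _tg_at_rh(rh, gt, isotherm) + offset - t_db

        f_lo, f_hi = residual(lo), residual(hi)
        if f_lo * f_hi > 0:
            warnings.warn(
                f"no sticky-point root in RH ({lo}, {hi}) at T_db = {t_db:.2f} K; "
                "point omitted",
                stacklevel=2,
            )
            continue
        rh_root = optimize.brentq(residual, lo, hi, xtol=1e-8)
        y = specific_humidity_from_rh(t_db, rh_root, pressure)
        points.append((float(t_db), float(y)))
        rhs.append(float(rh_root))
    return StickinessCurve(
        offset=offset, points=tuple(points), relative_humidities=tuple(rhs)
    )


def classify_zone(
    state: MoistAirState,
    gt: GordonTaylorParams,
    isotherm: SorptionIsotherm,
    offset: float = 10.0,
) -> ZoneLabel:
    """Classify a gas state against the material's plasticised glass transition.

    Safe for ``T_db < T_g`` (strict), transition up to ``T_g + offset``
    (boundary equality counts as transition, the conservative choice), risk
    beyond.
    """
    if state.supersaturated:
        raise ValueError(
            "supersaturated state: condensation regime, zone label undefined"
        )
    tg = _tg_at_rh(state.relative_humidity, gt, isotherm)
    t_db = state.dry_bulb_temperature
    if t_db < tg:
        return ZoneLabel.SAFE
    if t_db <= tg + offset:
        return ZoneLabel.TRANSITION
    return ZoneLabel.RISK


def dihydrate_risk(state: MoistAirState, rh_threshold: float = 0.44) -> bool:
    """Crystalline-dihydrate nucleation risk flag.

    True iff the state's relative humidity strictly exceeds ``rh_threshold``
    (default 44% RH, the nucleation threshold for trehalose dihydrate);
    equality is below risk by convention.
    """
    return state.relative_humidity > rh_threshold
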