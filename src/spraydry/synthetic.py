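"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one instrument stream of a spray-drying campaign:
levitated-droplet axis series following the d^2-law with a lock point,
multi-phase dryer sensor logs, multi-step TGA moisture-release curves,
lognormal-mixture particle-size distributions and sorption-isotherm data.
Defaults mirror the study conditions of the lab-scale campaign this package
models (5 uL droplets at 30 mg/mL solute, B-290-class gas flows, wt%-scale
moisture steps).

A single top-level seed fans out to per-generator substreams through fixed
``numpy.random.SeedSequence`` child indices, so adding a generator never
perturbs the streams of existing ones.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .dryer_model import DryerConfig, Phase, SensorLog, station_states
from .material_state import SorptionIsotherm, equilibrium_moisture
from .powder_qc import PsdSample, TgaCurve, LdStage
from .sdd import DropletSeries

__all__ = [
    "substream",
    "gen_droplet_series",
    "gen_process_log",
    "gen_tga_curve",
    "gen_psd",
    "gen_sorption_dataset",
]

# fixed substream indices of the top-level seed (the counter scheme):
_STREAMS = {
    "droplet": 0,
    "process_log": 1,
    "tga": 2,
    "psd": 3,
    "sorption": 4,
    "particle": 5,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Child RNG for one generator family under a top-level seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[name]])


def gen_droplet_series(
    d0: float = 2.13e-3,
    kappa: float = 4.5e-9,
    lock_time: float | None = 900.0,
    aspect_ratio: float = 1.15,
    noise_sigma: float = 0.0,
    sampling_rate: float = 1.0,
    duration: float = 1100.0,
    solute_concentration: float = 30.0,
    seed: int = 0,
) -> DropletSeries:
    """d^2-law droplet shrinkage with a lock point and optical noise.

    The volume-equivalent diameter squared decays as ``d0^2 - kappa t``
    until ``lock_time`` (None: shrinks to the end of the record), constant
    after. The defaults are a ~5 uL droplet (d0 = 2.13 mm) of a 30 mg/mL
    solution drying at kappa = 4.5e-9 m^2/s, locking once ~90% of the
    initial d^2 is gone (mean concentration then ~0.8 g/mL, approaching the
    density of the forming solid skin). Axes follow the fixed
    ``aspect_ratio = major/minor`` of the levitated oblate droplet;
    ``noise_sigma`` is the relative sd of multiplicative Gaussian noise on
    each measured axis.
    """
    if d0 <= 0 or kappa <= 0 or sampling_rate <= 0 or duration <= 0:
        raise ValueError("physical parameters must be positive")
    if lock_time is not None and lock_time <= 0:
        raise ValueError("lock time must be positive")
    if aspect_ratio < 1.0:
        raise ValueError("aspect ratio must be >= 1 (major/minor)")
    rng = substream(seed, "droplet")
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    d2 = d0 * d0 - kappa * t
    if lock_time is not None:
        d2_lock = d0 * d0 - kappa * lock_time
        if d2_lock <= 0:
            raise ValueError("droplet fully evaporates before the lock time")
        d2 = np.where(t >= lock_time, d2_lock, d2)
    keep = d2 > 0
    t, d2 = t[keep], d2[keep]
    d_eq = np.sqrt(d2)
    # oblate spheroid with a/b = aspect_ratio and equal volume:
    # a^2 b = d_eq^3  ->  a = d_eq * ratio^(1/3)
    major = d_eq * aspect_ratio ** (1.0 / 3.0)
    minor = major / aspect_ratio
    if noise_sigma > 0:
        major = major * (1.0 + noise_sigma * rng.standard_normal(len(t)))
        minor = minor * (1.0 + noise_sigma * rng.standard_normal(len(t)))
        minor = np.minimum(minor, major)  # keep the oblate convention
    v0 = (math.pi / 6.0) * d0**3
    return DropletSeries(
        time=t,
        major_axis=major,
        minor_axis=minor,
        initial_volume=v0,
        solute_concentration=solute_concentration,
    )


def gen_process_log(
    config: DryerConfig,
    phase_durations: dict[Phase, float] | None = None,
    sensor_noise: dict[str, float] | None = None,
    sampling_interval: float = 5.0,
    lag_time: float = 60.0,
    seed: int = 0,
) -> tuple[SensorLog, dict[Phase, tuple[float, float]]]:
    """Four-phase dryer sensor log with first-order transitions and noise.

    DAP runs without feed, PSP feeds pure solvent, PrP feeds the solution
    (same evaporation load; what changes is the solids), S switches the
    heater off. Channel targets per phase come from :func:`station_states`;
    transitions relax with time constant ``lag_time``. Returns the log and
    the ground-truth phase boundaries.
    """
    if phase_durations is None:
        phase_durations = {
            Phase.DAP: 600.0,
            Phase.PSP: 1800.0,
            Phase.PrP: 1800.0,
            Phase.S: 600.0,
        }
    if any(v <= 0 for v in phase_durations.values()):
        raise ValueError("phase durations must be positive")
    noise = {"T": 0.2, "RH": 0.002, "p": 20.0, "FR": 0.0}
    if sensor_noise:
        noise.update(sensor_noise)
    rng = substream(seed, "process_log")

    dry_cfg = DryerConfig(
        dry_gas_mass_flow=config.dry_gas_mass_flow,
        inlet_set_temperature=config.inlet_set_temperature,
        feed_rate=0.0,
        feed_water_fraction=config.feed_water_fraction,
        feed_solids_concentration=config.feed_solids_concentration,
        feed_density=config.feed_density,
        heat_loss_p4_p5=config.heat_loss_p4_p5,
        heat_loss_p5_p7=config.heat_loss_p5_p7,
        heat_loss_p7_p9=config.heat_loss_p7_p9,
        ambient_state=config.ambient_state,
        gas=config.gas,
    )
    amb = config.ambient_state

    def targets(cfg: DryerConfig, heater_on: bool) -> dict[str, float]:
        if not heater_on:
            return {
                "T_P3": amb.dry_bulb_temperature,
                "T_P5": amb.dry_bulb_temperature,
                "T_P9": amb.dry_bulb_temperature,
                "RH_P9": amb.relative_humidity,
                "FR": 0.0,
            }
        sts = {s.station_id: s.state for s in station_states(cfg)}
        return {
            "T_P3": sts["P3"].dry_bulb_temperature,
            "T_P5": sts["P5"].dry_bulb_temperature,
            "T_P9": sts["P9"].dry_bulb_temperature,
            "RH_P9": sts["P9"].relative_humidity,
            "FR": cfg.feed_rate,
        }

    phase_targets = {
        Phase.DAP: targets(dry_cfg, True),
        Phase.PSP: targets(config, True),
        Phase.PrP: targets(config, True),
        Phase.S: targets(dry_cfg, False),
    }

    rows = []
    t_now = 0.0
    boundaries: dict[Phase, tuple[float, float]] = {}
    state = dict(phase_targets[Phase.DAP])  # start equilibrated in DAP
    alpha = 1.0 - math.exp(-sampling_interval / lag_time)
    for phase in (Phase.DAP, Phase.PSP, Phase.PrP, Phase.S):
        dur = phase_durations[phase]
        tgt = phase_targets[phase]
        t_start = t_now
        n_steps = int(round(dur / sampling_interval))
        for _ in range(n_steps):
            for key in state:
                if key == "FR":
                    state[key] = tgt[key]  # feed pump switches instantly
                else:
                    state[key] += alpha * (tgt[key] - state[key])
            rows.append(
                {
                    "time_s": t_now,
                    "T_P3_R_C": state["T_P3"] - 273.15 + noise["T"] * rng.standard_normal(),
                    "T_P5_R_C": state["T_P5"] - 273.15 + noise["T"] * rng.standard_normal(),
                    "T_P9_R_C": state["T_P9"] - 273.15 + noise["T"] * rng.standard_normal(),
                    "RH_P9_R_pct": max(
                        (state["RH_P9"] + noise["RH"] * rng.standard_normal()) * 100.0,
                        0.0,
                    ),
                    "p_P9_R_Pa": amb.total_pressure + noise["p"] * rng.standard_normal(),
                    "FR_P11_R_mL_min": state["FR"] * 6e7,  # m^3/s -> mL/min
                    "phase": phase.value,
                }
            )
            t_now += sampling_interval
        boundaries[phase] = (t_start, t_now - sampling_interval)
    raw = pd.DataFrame(rows)
    from .dryer_model import parse_sensor_log

    return parse_sensor_log(raw), boundaries


def gen_tga_curve(
    components: Sequence[tuple[float, float, float]] = (
        (2.45, 55.0, 8.0),
        (1.88, 100.0, 5.0),
        (3.91, 140.0, 12.0),
    ),
    t_start_c: float = 20.0,
    t_end_c: float = 200.0,
    n_points: int = 721,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> TgaCurve:
    """Superposition of sigmoidal mass-loss steps.

    Each component is ``(loss_wt_pct, release_temp_C, width_C)``; the default
    three-step scenario releases unbound water below 80 degC, hydrate water
    near 100 degC and entrapped water above the glass transition, with step
    sizes echoing a cold-dried trehalose powder (2.45/1.88/3.91 wt%).
    """
    comps = list(components)
    total = sum(c[0] for c in comps)
    if total >= 100.0:
        raise ValueError("total mass loss must stay below 100%")
    for _, _, width in comps:
        if width <= 0:
            raise ValueError("step widths must be positive")
    rng = substream(seed, "tga")
    t_c = np.linspace(t_start_c, t_end_c, n_points)
    loss = np.zeros_like(t_c)
    for amp, center, width in comps:
        # logistic step, ~99% released within +/- 2.6 widths
        loss += amp * 1.0 / (1.0 + np.exp(-(t_c - center) / (width / 4.0)))
    if noise_sigma > 0:
        loss = loss + noise_sigma * rng.standard_normal(len(t_c))
        loss = np.maximum.accumulate(np.maximum(loss, 0.0))  # keep cumulative
    rel_mass = 1.0 - loss / 100.0
    rel_mass[0] = 1.0
    return TgaCurve(temperature=t_c + 273.15, relative_mass=rel_mass)


def gen_psd(
    modes: Sequence[tuple[float, float, float]] = ((4.0, 1.6, 1.0),),
    grid_min_um: float = 0.1,
    grid_max_um: float = 1000.0,
    n_bins: int = 100,
    stage: LdStage = LdStage.LD0,
    seed: int = 0,
) -> PsdSample:
    """Lognormal-mixture volume-weighted PSD on a log-spaced grid.

    Each mode is ``(median_um, geometric_sd, volume_fraction)``; fractions
    must sum to 1. The default single mode (median 4 um, sigma_g 1.6) is a
    well-dispersed spray-dried powder; add a coarse mode above ~20 um to
    emulate agglomeration.
    """
    modes = list(modes)
    if abs(sum(m[2] for m in modes) - 1.0) > 1e-9:
        raise ValueError("mode volume fractions must sum to 1")
    sizes = np.geomspace(grid_min_um, grid_max_um, n_bins) * 1e-6
    log_s = np.log(sizes)
    edges = np.empty(n_bins + 1)
    edges[1:-1] = (log_s[:-1] + log_s[1:]) / 2.0
    edges[0] = 2 * log_s[0] - edges[1]
    edges[-1] = 2 * log_s[-1] - edges[-2]
    from scipy.stats import norm

    dens = np.zeros(n_bins)
    for median_um, sigma_g, frac in modes:
        if median_um <= 0 or sigma_g <= 1.0:
            raise ValueError("mode medians must be positive and sigma_g > 1")
        mu = math.log(median_um * 1e-6)
        s = math.log(sigma_g)
        cdf = norm.cdf(edges, loc=mu, scale=s)
        dens += frac * np.diff(cdf)
    dens /= dens.sum()
    return PsdSample(sizes=sizes, volume_density=dens, stage=stage)


def gen_sorption_dataset(
    isotherm: SorptionIsotherm,
    n: int = 15,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Synthetic (water activity, moisture content) pairs from a GAB isotherm.

    Water activities span (0.05, 0.9); ``noise_sigma`` is the relative sd of
    multiplicative Gaussian noise on the moisture values.
    """
    if n < 4:
        raise ValueError("need at least 4 sorption points")
    rng = substream(seed, "sorption")
    a_w = np.linspace(0.05, 0.9, n)
    x = np.array([equilibrium_moisture(a, isotherm) for a in a_w])
    if noise_sigma > 0:
        x = x * (1.0 + noise_sigma * rng.standard_normal(n))
        x = np.maximum(x, 1e-9)
    return list(zip(a_w.tolist(), x.tolist()))
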