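"""Off-line powder characterisation: TGA moisture accounting, vacuum-drying
removal, particle-size quantiles and Hartigan dip-test agglomeration scoring.

Thermogravimetric residual moisture is read as cumulative mass loss at
reference temperatures (RM80 / RM110 / RM180, wt%): loss below 80 degC is
unbound surface water, the 80-110 degC increment tracks dehydration of the
crystalline dihydrate (two waters per host molecule, released near 97 degC)
and the 110-180 degC increment is moisture entrapped above the glass
transition. Particle agglomeration is scored with Hartigan's dip test on
volume-weighted size samples: agglomerated powders have multi-modal size
distributions, and ultrasound dispersion (LD0 -> LD2) should raise the
probability of unimodality.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TgaCurve",
    "MoistureSummary",
    "PsdSample",
    "DipResult",
    "VacuumDryingSeries",
    "LdStage",
    "residual_moisture_at",
    "dihydrate_content",
    "rm_reduction",
    "vacuum_removal_fraction",
    "psd_quantiles",
    "dip_statistic",
    "dip_null_distribution",
    "unimodality_probability",
    "resample_psd",
    "deagglomeration_report",
    "HYDRATE_WATER_FRACTION",
]

# stoichiometric water fraction of the crystalline dihydrate:
# 2 M_water / M_dihydrate = 2*18.015/378.33
M_WATER = 18.015
M_DIHYDRATE = 378.33
HYDRATE_WATER_FRACTION = 2.0 * M_WATER / M_DIHYDRATE


class LdStage(str, enum.Enum):
    """Laser-diffraction de-agglomeration protocol stage."""

    LD0 = "LD0"  # no ultrasound
    LD1 = "LD1"  # 1 x 30 s ultrasound
    LD2 = "LD2"  # 2 x 30 s ultrasound


# ---------------------------------------------------------------------------
# TGA


@dataclass(frozen=True)
class TgaCurve:
    """Thermogravimetric curve: relative mass vs temperature.

    ``temperature`` strictly increasing (K); ``relative_mass`` is the mass
    fraction of the initial sample mass, starting at 1.
    """

    temperature: np.ndarray
    relative_mass: np.ndarray
    heating_rate: float = 10.0  # K/min, metadata

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        m = np.asarray(self.relative_mass, dtype=float)
        if len(t) != len(m) or len(t) < 2:
            raise ValueError("need matching temperature/mass arrays, length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.any(m <= 0) or np.any(m > 1.0 + 1e-12):
            raise ValueError("relative mass must lie in (0, 1]")
        if abs(m[0] - 1.0) > 1e-9:
            raise ValueError("relative mass must start at 1")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "relative_mass", m)


@dataclass(frozen=True)
class MoistureSummary:
    """RM80/RM110/RM180 (wt%) and their increments.

    Mass loss is cumulative so rm80 <= rm110 <= rm180 and both deltas are
    non-negative.
    """

    rm80: float
    rm110: float
    rm180: float

    def __post_init__(self) -> None:
        if not (self.rm80 <= self.rm110 + 1e-12 and self.rm110 <= self.rm180 + 1e-12):
            raise ValueError("mass loss must be cumulative: rm80 <= rm110 <= rm180")

    @property
    def delta_rm110(self) -> float:
        return self.rm110 - self.rm80

    @property
    def delta_rm180(self) -> float:
        return self.rm180 - self.rm110


def residual_moisture_at(
    curve: TgaCurve,
    reference_temperatures: Sequence[float] = (353.15, 383.15, 453.15),
) -> MoistureSummary:
    """Cumulative mass loss (wt%) at the three reference temperatures.

    ``RM_T = (1 - relative_mass(T)) * 100`` with linear interpolation on the
    temperature grid; defaults are 80/110/180 degC in kelvin.
    """
    refs = list(reference_temperatures)
    if len(refs) != 3:
        raise ValueError("expected exactly three reference temperatures")
    t = curve.temperature
    for r in refs:
        if not (t[0] <= r <= t[-1]):
            raise ValueError(
                f"reference temperature {r} K outside curve range "
                f"[{t[0]}, {t[-1]}] K"
            )
    rm = [(1.0 - float(np.interp(r, t, curve.relative_mass))) * 100.0 for r in refs]
    return MoistureSummary(rm80=rm[0], rm110=rm[1], rm180=rm[2])


def dihydrate_content(delta_rm110: float) -> float:
    """Theoretical maximum crystalline dihydrate content (wt%).

    The 80-110 degC mass-loss increment is attributed to hydrate water; the
    dihydrate binds ``2 M_water / M_dihydrate`` (~9.52 wt%) of its mass as
    water, so ``content = delta_rm110 / 0.0952``.
    """
    if delta_rm110 < 0:
        raise ValueError("delta RM110 must be non-negative")
    return delta_rm110 / HYDRATE_WATER_FRACTION


def rm_reduction(rm_a: float, rm_b: float) -> float:
    """Relative residual-moisture reduction (%) from baseline ``rm_a`` to ``rm_b``."""
    if rm_a <= 0:
        raise ValueError("baseline residual moisture must be positive")
    return (rm_a - rm_b) / rm_a * 100.0


def vacuum_removal_fraction(vacuum_loss: float, rm80: float) -> tuple[float, bool]:
    """Vacuum-drying mass loss as a percentage of the unbound moisture RM80.

    Returns ``(fraction_pct, exceeds_unbound)``; values above 100% mean the
    vacuum step removed more than the TGA-unbound moisture (flagged, not an
    error — desorption kinetics differ between the two measurements).
    """
    if rm80 <= 0:
        raise ValueError("RM80 must be positive")
    if vacuum_loss < 0:
        raise ValueError("vacuum loss must be non-negative")
    frac = vacuum_loss / rm80 * 100.0
    return frac, frac > 100.0


@dataclass(frozen=True)
class VacuumDryingSeries:
    """Gravimetric vacuum-drying record: mass change (wt%) vs time (h)."""

    time: np.ndarray  # h
    mass_change: np.ndarray  # wt% of initial sample mass, cumulative
    weighing_error: float = 0.25  # wt%, scale of the balance repeatability

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        m = np.asarray(self.mass_change, dtype=float)
        if len(t) != len(m) or len(t) < 2:
            raise ValueError("need matching time/mass arrays, length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "mass_change", m)

    @property
    def end_reached(self) -> bool:
        """True when the last two weighings agree within the weighing error."""
        return abs(self.mass_change[-1] - self.mass_change[-2]) < self.weighing_error

    @property
    def end_value(self) -> float:
        """Final cumulative mass change, wt%."""
        return float(self.mass_change[-1])


# ---------------------------------------------------------------------------
# Particle size distributions


@dataclass(frozen=True)
class PsdSample:
    """Volume-weighted particle-size distribution on a log-spaced grid.

    ``sizes`` are bin-centre diameters (m), ``volume_density`` the volume
    fraction per bin (sums to 1).
    """

    sizes: np.ndarray
    volume_density: np.ndarray
    stage: LdStage = LdStage.LD0

    def __post_init__(self) -> None:
        s = np.asarray(self.sizes, dtype=float)
        f = np.asarray(self.volume_density, dtype=float)
        if len(s) != len(f) or len(s) == 0:
            raise ValueError("sizes and densities must match and be non-empty")
        if not np.all(np.diff(s) > 0):
            raise ValueError("size grid must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("volume densities must be non-negative")
        total = float(f.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"volume densities must sum to 1, got {total}")
        object.__setattr__(self, "sizes", s)
        object.__setattr__(self, "volume_density", f)


def psd_quantiles(psd: PsdSample, probs: Sequence[float] = (0.1, 0.5, 0.9)) -> list[float]:
    """Volume-weighted size quantiles (D10/D50/D90 by default).

    The cumulative volume distribution is inverted by linear interpolation in
    log-size; a single-bin distribution returns that bin's size for every
    probability.
    """
    for p in probs:
        if not 0.0 < p < 1.0:
            raise ValueError(f"probability {p!r} outside (0, 1)")
    if len(psd.sizes) == 1:
        return [float(psd.sizes[0])] * len(probs)
    log_s = np.log(psd.sizes)
    cum = np.cumsum(psd.volume_density)
    # mid-bin convention: the cumulative value at a bin centre is the mass of
    # all previous bins plus half of this bin's
    cum_mid = cum - psd.volume_density / 2.0
    return [float(np.exp(np.interp(p, cum_mid, log_s))) for p in probs]


# ---------------------------------------------------------------------------
# Hartigan dip test


def dip_statistic(sample: Sequence[float]) -> float:
    """Hartigan & Hartigan dip statistic of a 1-D sample.

    The dip is the maximum distance between the empirical CDF and the
    closest unimodal CDF, computed by the iterative greatest-convex-minorant
    / least-concave-majorant refinement of the candidate modal interval.
    Scale- and shift-invariant; at least ``1/(2n)`` for samples with two or
    more distinct values.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample must be finite")
    if x[0] == x[-1]:
        return 0.0  # point mass: the ECDF is itself unimodal
    return _dip_count_units(x, n) / (2.0 * n)


def _dip_count_units(x: np.ndarray, n: int) -> float:
    """Core dip iteration; returns the dip in ECDF-count units (2n * dip).

    1-based index arrays mirror the published algorithm: ``mn[j]`` is the
    previous touch point of the greatest convex minorant fitted up to j,
    ``mj[k]`` the next touch point of the least concave majorant from k.
    """
    xs = np.empty(n + 1)
    xs[1:] = x
    mn = np.empty(n + 1, dtype=np.int64)
    mj = np.empty(n + 1, dtype=np.int64)

    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xs[j] - xs[mnj]) * (mnj - mnmnj) < (
                xs[mnj] - xs[mnmnj]
            ) * (j - mnj):
                break
            mn[j] = mnmnj

    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (xs[k] - xs[mjk]) * (mjk - mjmjk) < (
                xs[mjk] - xs[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # count units; floor corresponds to 1/(2n)

    while True:
        # GCM touch points from high down to low, LCM from low up to high
        gcm = [0, high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        icx = len(gcm) - 1
        lcm = [0, low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        icv = len(lcm) - 1

        ig, ih = icx, icv
        d = 0.0
        if icx != 2 or icv != 2:
            ix, iv = icx - 1, 2
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # next point along the merged walk comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xs[gcmix] - xs[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xs[lcmiv] - xs[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > icv:
                    iv = icv
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d <= dip:
            return dip

        # dip of the convex-minorant side over [gcm[ig], low..]
        dip_l = 0.0
        for j in range(ig, icx):
            max_t = 1.0
            j_l, j_u = gcm[j + 1], gcm[j]
            if j_u > j_l and xs[j_u] != xs[j_l]:
                for jb in range(j_l, j_u + 1):
                    t = (jb - j_l + 1) - (xs[jb] - xs[j_l]) * (j_u - j_l) / (
                        xs[j_u] - xs[j_l]
                    )
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        # dip of the concave-majorant side
        dip_u = 0.0
        for j in range(ih, icv):
            max_t = 1.0
            j_l, j_u = lcm[j], lcm[j + 1]
            if j_u > j_l and xs[j_u] != xs[j_l]:
                for jb in range(j_l, j_u + 1):
                    t = (xs[jb] - xs[j_l]) * (j_u - j_l) / (
                        xs[j_u] - xs[j_l]
                    ) - (jb - j_l - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)
        low, high = gcm[ig], lcm[ih]
        if low == high:
            return dip


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its bootstrap probability of unimodality."""

    dip_statistic: float
    unimodality_probability: float
    n: int
    bootstrap_reps: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.unimodality_probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def dip_null_distribution(
    n: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Dip statistics of ``reps`` Uniform(0,1) samples of size n.

    The dip is scale/shift-invariant and the uniform is the canonical least
    favourable unimodal null, so this one distribution calibrates the test
    for any sample of size n.
    """
    return np.array(
        [dip_statistic(rng.uniform(size=n)) for _ in range(reps)], dtype=float
    )


def unimodality_probability(
    sample: Sequence[float],
    bootstrap_reps: int = 2000,
    seed: int = 0,
    null_dips: np.ndarray | None = None,
) -> DipResult:
    """Bootstrap probability of unimodality (dip-test p-value).

    ``p`` is the fraction of uniform-null samples of the same size whose dip
    is at least the observed dip. Deterministic for a fixed seed; a
    precomputed ``null_dips`` array (from :func:`dip_null_distribution`) can
    be supplied to amortise calibration across many tests of equal n.
    """
    if bootstrap_reps < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    x = np.asarray(sample, dtype=float)
    obs = dip_statistic(x)
    if null_dips is None:
        rng = np.random.default_rng(seed)
        null_dips = dip_null_distribution(len(x), bootstrap_reps, rng)
    p = float(np.mean(null_dips >= obs))
    return DipResult(
        dip_statistic=obs,
        unimodality_probability=p,
        n=len(x),
        bootstrap_reps=len(null_dips),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# De-agglomeration comparison


def resample_psd(psd: PsdSample, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` sizes (m) from a binned PSD, volume-weighted, log-domain.

    Bins are drawn with probability equal to their volume fraction, then the
    size is jittered uniformly within the bin in log-space so the dip test
    sees a sample from a piecewise-continuous density rather than a comb of
    point masses.
    """
    if n < 2:
        raise ValueError("need at least 2 resampled sizes")
    log_s = np.log(psd.sizes)
    if len(log_s) == 1:
        return np.full(n, float(psd.sizes[0]))
    # bin edges at log-midpoints, end bins mirrored
    mid = (log_s[:-1] + log_s[1:]) / 2.0
    lo = np.concatenate([[2 * log_s[0] - mid[0]], mid])
    hi = np.concatenate([mid, [2 * log_s[-1] - mid[-1]]])
    idx = rng.choice(len(log_s), size=n, p=psd.volume_density)
    u = rng.uniform(size=n)
    return np.exp(lo[idx] + u * (hi[idx] - lo[idx]))


@dataclass(frozen=True)
class DeagglomerationReport:
    """LD0 vs LD2 comparison: quantile shifts and dip-test ordering."""

    dip_ld0: DipResult
    dip_ld2: DipResult
    quantiles_ld0: tuple[float, float, float]
    quantiles_ld2: tuple[float, float, float]
    quantile_shift: tuple[float, float, float]  # LD2 - LD0, m
    hdt_increased: bool  # unimodality probability rose after dispersion


def deagglomeration_report(
    psd_ld0: PsdSample,
    psd_ld2: PsdSample,
    resample_n: int = 500,
    seed: int = 0,
    bootstrap_reps: int = 2000,
) -> DeagglomerationReport:
    """Compare a powder's PSD before and after ultrasound dispersion.

    Both PSDs must share a size grid. Dispersion of agglomerates should
    shift the upper quantiles down and raise the probability of unimodality
    (HDT_LD0 < HDT_LD2).
    """
    if len(psd_ld0.sizes) != len(psd_ld2.sizes) or not np.allclose(
        psd_ld0.sizes, psd_ld2.sizes
    ):
        raise ValueError("PSDs must share a common size grid")
    rng = np.random.default_rng(seed)
    s0 = resample_psd(psd_ld0, resample_n, rng)
    s2 = resample_psd(psd_ld2, resample_n, rng)
    null = dip_null_distribution(resample_n, bootstrap_reps, rng)
    d0 = unimodality_probability(s0, bootstrap_reps, seed=seed, null_dips=null)
    d2 = unimodality_probability(s2, bootstrap_reps, seed=seed, null_dips=null)
    q0 = tuple(psd_quantiles(psd_ld0))
    q2 = tuple(psd_quantiles(psd_ld2))
    shift = tuple(b - a for a, b in zip(q0, q2))
    return DeagglomerationReport(
        dip_ld0=d0,
        dip_ld2=d2,
        quantiles_ld0=q0,
        quantiles_ld2=q2,
        quantile_shift=shift,
        hdt_increased=d2.unimodality_probability > d0.unimodality_probability,
    )
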