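"""Single-droplet-drying analysis.

An acoustically levitated droplet is filmed while it dries; each frame
yields a binary mask from which an ellipse with matching second-order
central moments gives major/minor axes. Treating the droplet as an oblate
spheroid (equatorial diameter = major axis, polar = minor), surface area
and volume follow in closed form. The volume-equivalent diameter squared,
``d^2 = (6 V / pi)^(2/3)``, decays linearly in time during steady
evaporation (the d^2-law) at rate kappa, until the lock point where a solid
skin forms and shrinkage stops.

From kappa and the solid-phase density at the lock point the Peclet number
``Pe = kappa / (8 D_s)`` and the surface enrichment
``E = c_s/c_m ~ 1 + Pe/5 + Pe^2/100 + Pe^3/4000`` connect the drying
kinetics to the solute diffusivity ``D_s``; inverting the (monotone) cubic
recovers Pe, and thus D_s, from a measured enrichment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage import measure

__all__ = [
    "DropletSeries",
    "DryingCurve",
    "LockPoint",
    "PecletEstimate",
    "ellipse_from_moments",
    "spheroid_surface_volume",
    "drying_curve",
    "fit_evaporation_rate",
    "detect_lock_point",
    "peclet_number",
    "surface_enrichment",
    "invert_enrichment",
    "estimate_diffusivity",
]


@dataclass(frozen=True)
class DropletSeries:
    """Time series of droplet ellipse axes.

    ``time`` in s, axes in m (major >= minor per frame), plus the initial
    volume and solute concentration needed for mass bookkeeping.
    """

    time: np.ndarray
    major_axis: np.ndarray
    minor_axis: np.ndarray
    initial_volume: float  # m^3
    solute_concentration: float  # kg/m^3

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.major_axis, dtype=float)
        b = np.asarray(self.minor_axis, dtype=float)
        if not (len(t) == len(a) == len(b)):
            raise ValueError("time and axis arrays must have equal length")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("axes must be positive")
        if np.any(a < b - 1e-15):
            raise ValueError("major axis must be >= minor axis")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "major_axis", a)
        object.__setattr__(self, "minor_axis", b)

    @property
    def solute_mass(self) -> float:
        """Solute mass in the droplet, kg (conserved during drying)."""
        return self.solute_concentration * self.initial_volume


@dataclass(frozen=True)
class DryingCurve:
    """Geometric drying curve derived from a droplet series."""

    time: np.ndarray
    surface_area: np.ndarray  # m^2
    volume: np.ndarray  # m^3
    normalized_d2: np.ndarray  # d^2(t)/d^2(0), volume-equivalent diameter
    series: DropletSeries | None = None

    @property
    def equivalent_diameter_sq(self) -> np.ndarray:
        """Volume-equivalent diameter squared, m^2."""
        return np.cbrt(6.0 * self.volume / math.pi) ** 2


@dataclass(frozen=True)
class LockPoint:
    """Moment when a solid skin forms and shrinkage stops."""

    time: float
    volume_at_lock: float  # m^3
    mean_concentration: float  # c_m = solute mass / V(lock), kg/m^3
    index: int


@dataclass(frozen=True)
class PecletEstimate:
    """Bundle of mutually consistent Peclet-analysis quantities.

    Invariants (checked on construction): ``Pe = kappa / (8 D_s)`` and
    ``E = c_s / c_m`` with E the enrichment cubic evaluated at Pe.
    """

    kappa: float  # m^2/s
    peclet: float
    enrichment: float
    surface_concentration: float  # c_s, kg/m^3
    mean_concentration: float  # c_m, kg/m^3
    diffusivity: float  # D_s, m^2/s
    kappa_stderr: float | None = None
    flat_profile: bool = False

    def __post_init__(self) -> None:
        if self.flat_profile:
            return
        if not math.isclose(self.peclet, self.kappa / (8.0 * self.diffusivity), rel_tol=1e-12):
            raise ValueError("inconsistent estimate: Pe != kappa/(8 D_s)")
        if not math.isclose(
            self.enrichment,
            self.surface_concentration / self.mean_concentration,
            rel_tol=1e-9,
        ):
            raise ValueError("inconsistent estimate: E != c_s/c_m")


def ellipse_from_moments(
    binary_mask: np.ndarray, pixel_size: float = 1.0
) -> tuple[float, float, tuple[float, float]]:
    """Axes of the ellipse with the mask's second-order central moments.

    Multiple foreground components are reduced to the largest with a
    warning. Returns ``(major_axis, minor_axis, centroid)`` in physical
    units (full axis lengths, not semi-axes).
    """
    mask = np.asarray(binary_mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("empty mask: no foreground pixels")
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    if len(props) > 1:
        warnings.warn(
            f"mask has {len(props)} components; using the largest", stacklevel=2
        )
        props.sort(key=lambda p: p.area, reverse=True)
    p = props[0]
    cy, cx = p.centroid
    return (
        float(p.axis_major_length * pixel_size),
        float(p.axis_minor_length * pixel_size),
        (float(cy * pixel_size), float(cx * pixel_size)),
    )


def spheroid_surface_volume(major_axis: float, minor_axis: float) -> tuple[float, float]:
    """Surface area and volume of an oblate spheroid from its diameters.

    ``major_axis`` is the equatorial diameter ``a``, ``minor_axis`` the polar
    diameter ``b`` (a >= b). ``V = (pi/6) a^2 b``; the area uses the
    eccentricity form with a series branch near the sphere limit to avoid
    0/0.
    """
    a, b = major_axis, minor_axis
    if a <= 0 or b <= 0:
        raise ValueError("axes must be positive")
    if a < b:
        raise ValueError("major axis must be >= minor axis (oblate convention)")
    ra, rb = a / 2.0, b / 2.0  # semi-axes
    volume = (math.pi / 6.0) * a * a * b
    e2 = 1.0 - (rb * rb) / (ra * ra)
    if e2 < 1e-9:
        # sphere-limit series: A = 4 pi ra^2 (1 - e^2/3 + O(e^4)) truncated
        area = 4.0 * math.pi * ra * ra * (1.0 - e2 / 3.0)
    else:
        e = math.sqrt(e2)
        area = 2.0 * math.pi * ra * ra * (1.0 + ((1.0 - e2) / e) * math.atanh(e))
    return float(area), float(volume)


def drying_curve(series: DropletSeries) -> DryingCurve:
    """Compute the area/volume drying curve of a droplet series."""
    area = np.empty(len(series.time))
    vol = np.empty(len(series.time))
    for i, (a, b) in enumerate(zip(series.major_axis, series.minor_axis)):
        area[i], vol[i] = spheroid_surface_volume(a, b)
    d2 = np.cbrt(6.0 * vol / math.pi) ** 2
    return DryingCurve(
        time=series.time,
        surface_area=area,
        volume=vol,
        normalized_d2=d2 / d2[0],
        series=series,
    )


def fit_evaporation_rate(
    curve: DryingCurve,
    fit_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """d^2-law evaporation rate kappa (m^2/s) by OLS, with standard error.

    kappa is minus the slope of the volume-equivalent diameter squared over
    the fit window (which must precede the lock point — the caller chooses
    it). A non-negative slope (growing droplet) is an error.
    """
    t = curve.time
    d2 = curve.equivalent_diameter_sq
    if fit_window is not None:
        sel = (t >= fit_window[0]) & (t <= fit_window[1])
        t, d2 = t[sel], d2[sel]
    if len(t) < 5:
        raise ValueError("need at least 5 samples in the fit window")
    x = np.column_stack([np.ones_like(t), t])
    beta, _, _, _ = np.linalg.lstsq(x, d2, rcond=None)
    slope = float(beta[1])
    if slope >= 0:
        raise ValueError("non-negative d^2 slope: droplet not evaporating")
    resid = d2 - x @ beta
    dof = max(len(t) - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((t - t.mean()) ** 2))
    stderr = math.sqrt(s2 / sxx) if sxx > 0 else math.nan
    return -slope, stderr


def detect_lock_point(
    curve: DryingCurve,
    kappa: float,
    slope_fraction: float = 0.1,
    persistence: int = 5,
    slope_window: int | None = None,
) -> LockPoint | None:
    """Earliest sustained flattening of the d^2 curve.

    The lock point is the first sample where the local d^2 slope magnitude
    stays below ``slope_fraction * kappa`` for ``persistence`` consecutive
    samples. Returns None when no such plateau exists (droplet evaporated to
    the end of the record).

    By default the local slope is the adjacent-sample difference, which is
    only usable on clean data: optical noise inflates single-step slopes far
    beyond the threshold. For noisy series pass ``slope_window`` to estimate
    each local slope by least squares over that many forward samples (lock
    time then resolves to roughly ``slope_fraction * slope_window`` samples).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    t = curve.time
    d2 = curve.equivalent_diameter_sq
    if slope_window is None:
        slopes = np.diff(d2) / np.diff(t)  # slope of segment i -> i+1
    else:
        w = slope_window
        if w < 3 or w > len(t):
            raise ValueError("slope window must be in [3, series length]")
        slopes = np.array(
            [
                np.polyfit(t[i : i + w], d2[i : i + w], 1)[0]
                for i in range(len(t) - w + 1)
            ]
        )
    flat = np.abs(slopes) < slope_fraction * kappa
    run = 0
    for i, ok in enumerate(flat):
        run = run + 1 if ok else 0
        if run >= persistence:
            idx = i - persistence + 1
            series = curve.series
            if series is None:
                raise ValueError("curve lacks its source series (solute mass unknown)")
            v_lock = float(curve.volume[idx])
            return LockPoint(
                time=float(t[idx]),
                volume_at_lock=v_lock,
                mean_concentration=series.solute_mass / v_lock,
                index=idx,
            )
    return None


def peclet_number(kappa: float, diffusivity: float) -> float:
    """``Pe = kappa / (8 D_s)``."""
    if kappa <= 0 or diffusivity <= 0:
        raise ValueError("kappa and diffusivity must be positive")
    return kappa / (8.0 * diffusivity)


#: Pe above which the steady-state enrichment polynomial loses validity
PE_VALIDITY_LIMIT = 20.0


def surface_enrichment(peclet: float) -> float:
    """Surface enrichment ``E = 1 + Pe/5 + Pe^2/100 + Pe^3/4000``.

    Strictly increasing in Pe with E(0) = 1. Warns (does not fail) above
    Pe = 20, the edge of the steady-state approximation's validity.
    """
    if peclet < 0:
        raise ValueError("Peclet number must be non-negative")
    if peclet > PE_VALIDITY_LIMIT:
        warnings.warn(
            f"Pe = {peclet:.3g} above the validity limit ({PE_VALIDITY_LIMIT}) "
            "of the enrichment approximation",
            stacklevel=2,
        )
    return 1.0 + peclet / 5.0 + peclet**2 / 100.0 + peclet**3 / 4000.0


def invert_enrichment(enrichment: float) -> float:
    """Unique non-negative Pe with ``surface_enrichment(Pe) = enrichment``.

    The cubic is strictly increasing for Pe >= 0, so bisection is exact;
    tolerance 1e-10 on Pe.
    """
    if enrichment < 1.0:
        raise ValueError("enrichment must be >= 1 (E = c_s/c_m with c_s >= c_m)")
    if enrichment == 1.0:
        return 0.0

    def f(pe: float) -> float:
        return 1.0 + pe / 5.0 + pe**2 / 100.0 + pe**3 / 4000.0 - enrichment

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))


def estimate_diffusivity(
    kappa: float,
    lock: LockPoint,
    surface_concentration: float,
    kappa_stderr: float | None = None,
) -> PecletEstimate:
    """Solute diffusivity from the drying rate and lock-point concentrations.

    ``E = c_s / c_m`` with ``c_s`` the solid-phase density at skin formation
    (e.g. from tomography) and ``c_m`` the mean concentration at the lock
    point; Pe from inverting the enrichment cubic, then
    ``D_s = kappa / (8 Pe)``. When ``c_s = c_m`` exactly (flat profile) Pe=0
    and D_s is unbounded; that degenerate case is returned flagged instead
    of dividing by zero.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    c_m = lock.mean_concentration
    c_s = surface_concentration
    if c_s < c_m:
        raise ValueError("surface concentration below mean: non-physical enrichment")
    e = c_s / c_m
    pe = invert_enrichment(e)
    if pe == 0.0:
        return PecletEstimate(
            kappa=kappa,
            peclet=0.0,
            enrichment=1.0,
            surface_concentration=c_s,
            mean_concentration=c_m,
            diffusivity=math.inf,
            kappa_stderr=kappa_stderr,
            flat_profile=True,
        )
    d_s = kappa / (8.0 * pe)
    return PecletEstimate(
        kappa=kappa,
        peclet=pe,
        enrichment=e,
        surface_concentration=c_s,
        mean_concentration=c_m,
        diffusivity=d_s,
        kappa_stderr=kappa_stderr,
    )
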