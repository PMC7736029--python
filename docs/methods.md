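# Methods

`spraydry` models the process-development workflow for spray drying
heat-sensitive formulations (a sugar excipient, a peptide, and their
formulation) on a lab-scale open-loop dryer: where may the dryer be operated
without the product sticking, crystallising or staying wet, and what do
single-droplet experiments and powder QC say about the particles produced.

## Moist-air bookkeeping

All internal units are SI (K, Pa, kg, s); Celsius, %RH, mL/min and µm appear
only at I/O boundaries. Specific humidity `Y` (kg water per kg **dry** gas) is
the conserved bookkeeping variable of the open loop: the dry-gas mass flow is
constant from intake to exhaust, so evaporating `ṁ_evap` simply adds
`ṁ_evap/ṁ_gas` to `Y`. Saturation vapour pressure uses the Magnus-form Buck
correlation (`611.21·exp((18.678 − t/234.5)·t/(257.14 + t))` Pa, `t` in °C),
accurate to well under 0.5 % against steam tables over 0–130 °C; the steam
table appears only as a test oracle. Evaporative cooling is
`ΔT = ṁ_evap·Δh_vap/(ṁ_gas·c_p,humid)` with the humid heat capacity evaluated
at the **inlet** humidity — the difference to a mean-humidity convention is
far below sensor noise at the humidity levels involved. Supersaturated states
(RH > 1) are flagged, never clipped: condensation in the cyclone is a failure
mode the workflow must detect.

## Glass transition, sorption and the stickiness curve

The plasticised glass transition follows the Gordon–Taylor mixing rule
`T_g = (w_s·T_g,s + K·w_w·T_g,w)/(w_s + K·w_w)` with wet-basis water fraction
`w_w`. The shipped trehalose–water parameter set uses component values
`T_g,s = 389 K`, `T_g,w = 136 K` and `K = 6.04`; `fit_gordon_taylor` re-estimates
`K` (endpoints fixed) by nonlinear least squares and reports its standard
error from the Gauss–Newton curvature.

Moisture uptake versus gas humidity uses a GAB isotherm
`X(a_w) = X_m·C·k·a_w/((1 − k·a_w)(1 − k·a_w + C·k·a_w))`, dry basis. The
shipped trehalose parameters (`X_m = 0.065`, `C = 10`, `k = 0.89`) are
calibration placeholders of realistic shape and scale, intended to be refit
from user sorption data with `fit_isotherm` (initialised from a moment-style
guess, bounded `k ≤ 1.05`). Isotherms are dry-basis; the explicit conversion
`w_w = X/(1+X)` feeds Gordon–Taylor.

The stickiness curve solves, at each dry-bulb temperature on a grid,
`T_g(w_w(X(RH))) + offset = T_db` for RH. The left side is strictly
decreasing in RH, so Brent bisection on RH ∈ (1e-6, 0.999) with 1e-8
tolerance is guaranteed to converge; grid points with no root are dropped
with a warning. The sticky-point offset defaults to 10 K (the curve drawn on
the design-space chart), with the 15 ± 5 K literature band available through
the `offset` argument. Zone classification is conservative: `safe` is strict
`T_db < T_g`; the boundary `T_db = T_g` already counts as `transition`;
`risk` starts strictly above `T_g + offset`. Dihydrate nucleation risk is a
strict `RH > 0.44` flag (equality is not risk).

Ethanol co-solvent is tracked only as feed composition; psychrometrics and
charting are water-only. Ethanol is a stronger plasticiser than water
(`T_g ≈ 97 K`), so water-only charts are optimistic for high-ethanol feeds —
a known limitation, handled qualitatively, not charted.

## Dryer station model

Stations: P1 ambient intake → P3 heated inlet (set point, ambient humidity)
→ P4 post-atomisation (full humidity gain, evaporative cooling) → P5 column
exit → P7 collection → P9 exhaust sensor. Evaporation is assumed complete by
P4 (droplet drying is fast near the nozzle at lab scale); wall heat losses
P4→P5→P7→P9 are lumped constants per segment (defaults 25/10/5 K chosen to
mimic non-jacketed lab glassware; calibrate from dry-air-phase data where
available). Water mass is conserved across stations to machine precision by
construction.

The feasible-operation map is an ordinary-least-squares full quadratic
`RH_P9(feed rate, inlet T)`; runs that failed (wall film, condensation) are
excluded from the fit but retained, and the operation limit band is
`[max RH among passed, min RH among failed]`, with inversions reported as an
overlap warning rather than masked.

The cyclone cut size uses the Barth equilibrium-orbit model,
`d₅₀ = sqrt(9 µ Q/(π H Δρ v_θ²))`, with the control-surface tangential
velocity from a loss-free vortex spun up by the inlet jet,
`v_θ = (Q/ab)·(D − b)/D_x`. It scales as `Q^(−1/2)` and `Δρ^(−1/2)`; the
geometry is fully configurable so the model can be calibrated to a measured
cut size for a specific dryer.

Yield is moisture-compensated, `yield = m_product(1 − RM₁₈₀)/(c_feed·V_feed)`;
values above 1 are flagged as accounting anomalies, not clamped.

Sensor logs (CSV contract: `time_s, T_P3_R_C, T_P5_R_C, T_P9_R_C,
RH_P9_R_pct, p_P9_R_Pa, FR_P11_R_mL_min[, phase]`) are segmented on the
feed-rate channel: dry-air → solvent at the first sustained non-zero feed,
feeding → shut-down at the first sustained feed-off; the solvent→solution
switch is operator knowledge and must be supplied (no sensor distinguishes
the two liquids). Steady-state windows require sd(RH) < 1 %RH and
sd(T) < 1 K (5-min rolling default). The filter check reports
`max|p(0) − p(t)|/p_baseline` against a 5 % threshold.

## Single-droplet drying

Droplet masks reduce to the ellipse with equal second-order central moments
(via `skimage.regionprops`; full axis length = 4·√eigenvalue). The levitated
droplet flattens axially, so the major axis is taken as the equatorial
diameter and the minor as the polar diameter of an oblate spheroid
(`V = (π/6)a²b`; closed-form area with a series branch near the sphere limit
to avoid 0/0). The d²-law regression variable is the **volume-equivalent**
diameter squared, `d² = (6V/π)^(2/3)` — the standard choice; κ is minus its
OLS slope before the lock point. The lock point is the earliest time where
the local d² slope magnitude stays below `0.1·κ` for 5 consecutive samples
(both thresholds configurable; the persistence guards against noise-induced
false plateaus).

Péclet analysis: `Pe = κ/(8 D_s)`; surface enrichment
`E = c_s/c_m ≈ 1 + Pe/5 + Pe²/100 + Pe³/4000`, valid for Pe ≤ 20 (warned,
not refused, above — measured systems sit near 19). The cubic is strictly
increasing, so `invert_enrichment` bisects to 1e-10. `estimate_diffusivity`
sets `E = c_s/c_m` with `c_s` taken as the tomography-derived solid density
at skin formation, inverts for Pe and returns `D_s = κ/(8 Pe)`; every
returned estimate satisfies both identities to 1e-12/1e-9 by construction.
`c_s = c_m` (flat profile, Pe = 0) returns a flagged degenerate result
instead of dividing by zero. Reported ± uncertainties are expected to come
from replicate spread; the κ standard error is carried through for reference.

## Voxel morphology

Descriptors on binarised tomography masks: sphericity
`ψ = π^(1/3)(6 V_ROI)^(2/3)/A_ROI`, solidity `V_solid/V_ROI`, convexity
`V_ROI/V_CH`, solid density `ρ = m/V_solid`. The ROI fills enclosed cavities
by 26-connected background flood fill against the 6-connected solid (the
complementary connectivity pair that avoids tunnel paradoxes); cavities open
to the outside stay open. Volumes in ψ and solidity are voxel counts ×
voxel volume. Surface area comes from a marching-cubes isosurface after a
σ = 1 voxel Gaussian pre-smoothing: raw voxel-face counting overestimates a
ball's area by ~50 %, raw marching cubes by ~9 %, while the smoothed mesh is
within a fraction of a percent at radius ≥ 20 voxels. The convexity ratio is
evaluated entirely on the mesh — mesh-enclosed volume over the volume of the
convex hull of the mesh vertices — which bounds convexity ≤ 1 by
construction; mixing a voxel-count numerator with a point-hull denominator
drifts above 1 by half-voxel mismatch. Digitised-ball validation bands:
ψ ∈ [0.97, 1.01], convexity ∈ [0.97, 1.0], mesh area within 3 % of analytic.

The particle generator produces solid balls, hollow shells with a prescribed
cavity volume fraction, and buckled particles (seeded cosine-mode radial
perturbation of given degree and relative amplitude; amplitude 0 reduces
exactly to the ball). Deep buckling can shear off shards; the largest
6-connected component is kept.

## Powder QC

TGA curves are read as cumulative mass loss with linear interpolation in
temperature; RM₈₀/RM₁₁₀/RM₁₈₀ are the losses at 80/110/180 °C (loss below
80 °C ≈ unbound water; the 80→110 °C increment tracks dihydrate dehydration
near 97 °C; 110→180 °C is entrapped moisture above the dry glass
transition). The dihydrate upper bound divides ΔRM₁₁₀ by the stoichiometric
water fraction `2·18.015/378.33 ≈ 0.0952`; published estimates rounded from
slightly different intermediates, so comparisons carry a 2 % relative
tolerance. Vacuum-drying removal is reported as a percentage of RM₈₀ and may
exceed 100 % (flagged — desorption kinetics differ between a 10 K/min ramp
and 300 h at 50 °C/20 mbar).

PSD quantiles (D₁₀,₃/D₅₀,₃/D₉₀,₃) invert the cumulative volume distribution
by linear interpolation in log-size with a mid-bin convention.

The Hartigan dip statistic (largest distance between the empirical CDF and
the closest unimodal CDF) is implemented with the classical iterative
greatest-convex-minorant / least-concave-majorant refinement of the modal
interval, and is validated in the test suite against an independent exact
oracle: a linear program over piecewise-linear unimodal CDFs with an atom
allowed at the mode, checked for equality on a seeded battery of small-n
samples including ties. The probability of unimodality is the fraction of
Uniform(0,1) null samples of equal size whose dip meets or exceeds the
observed one (the canonical calibration; 2000 replicates by default,
seeded). Because the null depends only on n, `dip_null_distribution` lets
many tests of equal size share one calibration. De-agglomeration scoring
resamples volume-weighted sizes in the log domain (n = 500 default), with
uniform jitter within each bin so the test sees a sample from a
piecewise-continuous density rather than a comb of point masses.

## Synthetic data

Generators emulate every input stream under the study conditions: ~5 µL
droplets (d₀ = 2.13 mm) of 30 mg/mL solute drying at κ = 4.5e-9 m²/s with a
lock point and multiplicative optical noise; four-phase dryer logs
(dry-air → solvent → production → shut-down) whose per-phase targets come
from the station model, with first-order lag transitions and additive sensor
noise; sigmoidal multi-step TGA curves (default steps 2.45/1.88/3.91 wt% at
55/100/140 °C, a cold-dried sugar powder); lognormal-mixture PSDs (default
median 4 µm, σ_g 1.6); and GAB sorption points over a_w ∈ (0.05, 0.9). A
single top-level seed fans out to fixed per-generator substreams via
`SeedSequence.spawn`, so adding a generator never perturbs existing streams.

What the generators do **not** emulate: droplet oscillation and acoustic
streaming, internal concentration fields (the d²-law break is imposed, not
simulated), sensor drift and recalibration steps, multi-component TGA
overlap with solvent loss, and grayscale/partial-volume effects in
tomography. Passing tests therefore demonstrate correctness of the analysis
chain under its stated model, not robustness to every instrument artefact.

## Numerical choices and limitations

- Root finding is bisection/Brent on provably monotone problems throughout;
  tolerances: stickiness RH 1e-8, enrichment inversion 1e-10.
- OLS fits use `numpy.linalg.lstsq`; nonlinear fits `scipy.curve_fit` with
  documented initialisation and bounds.
- Acceptance-scale simulation sizes (1000 type-I replicates at n = 100 with a
  2000-sample shared null; 600-sample droplet series) keep every check well
  under a minute while leaving Monte-Carlo error far inside the asserted
  bands.
- The dip statistic of an all-equal sample is 0 (a point mass is unimodal);
  the 1/(2n) lower bound applies once two distinct values exist.
- The station model is steady-state and lumped; it does not resolve axial
  profiles, droplet-size distributions or closed-loop (inert gas) operation.
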