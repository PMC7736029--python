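# spraydry

Data-driven process development for lab-scale spray drying of heat-sensitive
formulations (sugar excipients, peptides and their blends). The package turns
the instrument streams of a development campaign — levitated single-droplet
videos, dryer sensor logs, thermogravimetric curves, laser-diffraction size
distributions and micro-tomography masks — into the quantities a formulator
steers by: a psychrometric design space with stickiness zones, droplet-scale
Péclet/surface-enrichment estimates, 3-D particle shape descriptors and
powder QC metrics. Seeded synthetic generators emulate every input stream, so
the full pipeline runs and is tested without any instrument data.

## The models at the core

**Design space.** Moist-air states are tracked as specific humidity
Y (kg water / kg dry gas) through the dryer stations P1→P9 (mass balance
`Y_out = Y_in + ṁ_evap/ṁ_gas`, evaporative cooling
`ΔT = ṁ_evap·Δh_vap/(ṁ_gas·c_p)`). The product sticks when the local dry-bulb
temperature exceeds the moisture-plasticised glass transition, predicted by
the Gordon–Taylor rule

    T_g = (w_s·T_g,s + K·w_w·T_g,w) / (w_s + K·w_w)

(trehalose–water: T_g,s = 389 K, T_g,w = 136 K, K = 6.04) with the water
fraction from a GAB sorption isotherm at the local relative humidity.
Solving `T_g + offset = T_db` traces the stickiness curve on the
psychrometric chart and splits it into safe (`T_db < T_g`), transition and
risk (`T_db > T_g + 10 K`) zones, with a separate dihydrate-nucleation flag
above 44 %RH.

**Particle formation.** A drying droplet follows the d²-law; the
volume-equivalent diameter squared shrinks linearly at rate κ until a solid
skin forms (lock point). The Péclet number `Pe = κ/(8·D_s)` sets the surface
enrichment `E = c_s/c_m ≈ 1 + Pe/5 + Pe²/100 + Pe³/4000`; inverting the
cubic at the measured enrichment (surface concentration from tomography
solid density) yields the solute diffusivity. Low Pe → dense spherical
particles; Pe ≫ 1 → early skin formation and buckling.

**Powder QC.** Residual moisture is read from TGA curves at 80/110/180 °C
(unbound / hydrate-bound / entrapped water); the 80→110 °C increment bounds
the crystalline dihydrate content via its 9.52 wt% stoichiometric water.
Agglomeration is scored with Hartigan's dip test (probability of
unimodality, bootstrap-calibrated against a uniform null) on volume-weighted
size samples before and after ultrasound dispersion.

## Worked example

Simulate a single-droplet experiment and analyse it:

```
$ spraydry simulate droplet --seed 3 --out demo/
$ spraydry sdd --series demo/droplet.csv --c0-mg-ml 30 --v0-ul 5.05 \
      --cs-mg-ml 1500 --out demo/sdd.json
$ cat demo/sdd.json
{
  "kappa_m2_s": 4.500517223925087e-09,
  "kappa_stderr": 2.6874879489893868e-12,
  "lock_point": {
    "time_s": 885.0,
    "volume_m3": 2.164171174628913e-10,
    "mean_concentration_mg_mL": 700.0370477902584
  },
  "peclet": 4.5570759598634965,
  "enrichment": 2.1427437372563496,
  "diffusivity_m2_s": 1.234486012402319e-10
}
```

The droplet dried at κ ≈ 4.5e-9 m²/s and locked at t ≈ 885 s, by which
point the mean solute concentration had risen to ~0.70 g/mL. With the
solid-phase density 1.5 g/mL as the surface concentration, the enrichment
E ≈ 2.14 inverts to Pe ≈ 4.6 and a diffusivity D_s ≈ 1.2e-10 m²/s — a
low-Péclet, dense-particle regime typical of small-sugar solutes.

Powder QC on a synthetic three-step TGA curve:

```
$ spraydry simulate tga --seed 3 --out demo/
$ spraydry qc tga --in demo/tga.csv
RM80 2.45 wt% | RM110 4.33 wt% | RM180 8.24 wt%
dRM110 1.88 wt% -> dihydrate <= 19.74 wt%
```

A cold-dried powder holding 8.24 wt% total moisture, whose 1.88 wt%
hydrate-release step bounds the crystalline dihydrate at ~20 wt%.

Library use mirrors the CLI; see `docs/methods.md` for the model details,
parameter defaults and numerical choices.

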