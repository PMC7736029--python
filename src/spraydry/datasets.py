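"""Published residual-moisture table of the spray-drying campaign.

Per-experiment thermogravimetric mass loss at 80/110/180 degC (wt%), the
gravimetric vacuum-drying loss (wt%) and, for the trehalose runs, the
measured glass transition of the powder (degC). SPT rows are trehalose
experiments, SPG rows glucagon (SPG5 the glucagon-trehalose formulation;
its 180 degC value is unusable because the formulation browns above
~170 degC). These printed values are inputs to the moisture-accounting
operations, not outputs of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MoistureRow", "RESIDUAL_MOISTURE_TABLE"]


@dataclass(frozen=True)
class MoistureRow:
    rm80: float  # wt% TGA loss at 80 degC
    rm110: float  # wt% at 110 degC
    rm180: float | None  # wt% at 180 degC (None where not measurable)
    vacuum_loss: float  # wt% gravimetric loss during vacuum drying
    tg_c: float | None = None  # powder glass transition, degC (TRE runs only)


RESIDUAL_MOISTURE_TABLE: dict[str, MoistureRow] = {
    "SPT1": MoistureRow(2.45, 4.33, 8.24, 6.34, 42.35),
    "SPT2": MoistureRow(3.81, 4.10, 4.13, 3.10, 60.26),
    "SPT3": MoistureRow(4.78, 5.82, 6.48, 4.70, 40.32),
    "SPT4": MoistureRow(3.57, 3.87, 3.90, 2.25, 65.12),
    "SPT5": MoistureRow(4.77, 4.90, 5.58, 4.28, 38.98),
    "SPT6": MoistureRow(3.80, 3.99, 4.49, 2.61, 57.16),
    "SPG1": MoistureRow(3.99, 4.27, 7.81, 4.15),
    "SPG2": MoistureRow(3.77, 4.07, 7.82, 3.55),
    "SPG3": MoistureRow(3.78, 4.19, 8.08, 3.42),
    "SPG4": MoistureRow(4.85, 5.14, 8.72, 5.05),
    "SPG5": MoistureRow(4.38, 7.16, None, 5.83),
}
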