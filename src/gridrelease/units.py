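"""Unit conversions and rounding, centralized.

Conventions used throughout the package: lengths in mm, areas in cm²,
masses in mg, concentrations in mg/L, volumes in mL, specific surface
area in cm²/g, profile times in days (raw sampling records in hours).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

MM2_PER_CM2 = 100.0
HOURS_PER_DAY = 24.0
MG_PER_G = 1000.0
NG_PER_MG = 1e6
ML_PER_L = 1000.0


def mm2_to_cm2(area_mm2: float) -> float:
    return area_mm2 / MM2_PER_CM2


def hours_to_days(t_h: float) -> float:
    return t_h / HOURS_PER_DAY


def conc_vol_to_mass_mg(conc_mg_per_l: float, volume_ml: float) -> float:
    """Mass (mg) dissolved in ``volume_ml`` at ``conc_mg_per_l``."""
    return conc_mg_per_l * volume_ml / ML_PER_L


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables do.

    Python's built-in ``round`` is banker's rounding; table comparisons in
    this package always use half-up.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
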