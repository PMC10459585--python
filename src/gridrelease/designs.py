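"""Bundled design library: the nine-implant dissolution study set.

One record per printed grid inlay of the long-term dissolution study,
holding the design parameters, the mean inlay mass, the measured
(micro-CT) drug-eluting surface area and, for reference, the published
derived quantities (dose, calculated area, area ratio, SSA).  Derived
columns are recomputed by :func:`design_report`; the published numbers
are retained so that consistency can be checked, not assumed.

A library can also be loaded from a YAML/JSON file with the same keys.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import geometry
from .geometry import DEFAULT_DRUG_LOAD_FRACTION, NetworkDesign
from .units import round_half_up


@dataclass(frozen=True)
class ImplantRecord:
    """One implant design plus its physical measurements."""

    name: str
    strand_width: float  # mm
    pore_size: float  # mm
    footprint: float  # mm, square inlays
    height: float  # mm
    mass_mg: float
    mass_sd_mg: float
    area_true_cm2: float  # micro-CT measurement (n = 1), supplied as input
    # published reference values (not recomputed here):
    dose_ref_mg: float
    area_calc_ref_cm2: float
    ratio_ref: float
    ssa_ref_cm2_per_g: float

    @property
    def design(self) -> NetworkDesign:
        return NetworkDesign(
            name=self.name,
            strand_width=self.strand_width,
            pore_size_xy=self.pore_size,
            footprint_x=self.footprint,
            footprint_y=self.footprint,
            height=self.height,
        )


#: The nine strand-width × pore-size combinations of the study.
STUDY_IMPLANTS: tuple[ImplantRecord, ...] = (
    ImplantRecord("0.4 × 0.4", 0.4, 0.4, 14.0, 3.2, 327.0, 21.5, 20.54, 29.1, 23.02, 0.89, 62.6),
    ImplantRecord("0.4 × 0.8", 0.4, 0.8, 14.0, 3.2, 222.1, 16.0, 18.54, 19.7, 16.93, 1.10, 83.5),
    ImplantRecord("0.4 × 1.2", 0.4, 1.2, 14.0, 3.2, 146.4, 19.9, 13.08, 13.0, 12.45, 1.05, 89.3),
    ImplantRecord("0.8 × 0.4", 0.8, 0.4, 14.8, 3.2, 517.3, 18.3, 12.95, 45.8, 15.78, 0.82, 25.0),
    ImplantRecord("0.8 × 0.8", 0.8, 0.8, 15.2, 3.2, 385.12, 28.8, 15.30, 34.1, 13.31, 1.15, 39.7),
    ImplantRecord("0.8 × 1.2", 0.8, 1.2, 15.2, 3.2, 272.1, 10.3, 13.08, 24.1, 10.89, 1.20, 48.1),
    ImplantRecord("1.2 × 0.4", 1.2, 0.4, 13.2, 3.6, 491.4, 7.7, 9.80, 43.5, 10.25, 0.96, 19.9),
    ImplantRecord("1.2 × 0.8", 1.2, 0.8, 12.8, 3.6, 241.7, 4.7, 8.69, 30.5, 8.06, 1.08, 25.4),
    ImplantRecord("1.2 × 1.2", 1.2, 1.2, 13.2, 3.6, 316.0, 9.7, 7.91, 28.0, 7.27, 1.09, 25.0),
)

#: Records whose published mass/dose/SSA triple is internally inconsistent
#: and therefore excluded from exact-agreement checks: the 1.2 × 0.8 inlay
#: (dose and SSA imply a mass of ~342–344 mg, not 241.7 mg), the 0.4 × 0.4
#: SSA (62.6 published vs 62.8 from the mean mass — probably computed with
#: the single CT-scanned unit's mass) and the 0.4 × 0.4 dose (29.1
#: published vs 29.0 from 327.0 mg × 0.08858 at 1 d.p.).
INCONSISTENT_CELLS: frozenset[tuple[str, str]] = frozenset(
    {("1.2 × 0.8", "dose"), ("1.2 × 0.8", "ssa"),
     ("0.4 × 0.4", "ssa"), ("0.4 × 0.4", "dose")}
)


def get_implant(name: str) -> ImplantRecord:
    for rec in STUDY_IMPLANTS:
        if rec.name == name:
            return rec
    raise KeyError(f"unknown implant design {name!r}")


def load_design_library(path: str | Path) -> list[ImplantRecord]:
    """Read a design library from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return [ImplantRecord(**rec) for rec in data]


def dump_design_library(records: list[ImplantRecord], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump([asdict(r) for r in records], sort_keys=False))


def design_report(records: tuple[ImplantRecord, ...] | list[ImplantRecord] = STUDY_IMPLANTS,
                  drug_load_fraction: float = DEFAULT_DRUG_LOAD_FRACTION) -> pd.DataFrame:
    """Recompute the derived physical-property table for a design library.

    Dose comes from inlay mass × drug load fraction, SSA from the measured
    area and the mass, and the area ratio from measured over published
    calculated area; values are rounded half-up to the printed precision.
    """
    rows = []
    for rec in records:
        phys = geometry.characterize(
            mass_mg=rec.mass_mg,
            area_true_cm2=rec.area_true_cm2,
            area_calc_cm2=rec.area_calc_ref_cm2,
            drug_load_fraction=drug_load_fraction,
            design=rec.design,
            mass_sd_mg=rec.mass_sd_mg,
        )
        rows.append({
            "implant": rec.name,
            "strand_width_mm": rec.strand_width,
            "pore_size_mm": rec.pore_size,
            "footprint_mm": rec.footprint,
            "height_mm": rec.height,
            "mass_mg": rec.mass_mg,
            "dose_mg": round_half_up(phys.dose_mg, 1),
            "area_calc_cm2": rec.area_calc_ref_cm2,
            "area_true_cm2": rec.area_true_cm2,
            "area_ratio": round_half_up(phys.area_ratio, 2),
            "ssa_cm2_per_g": round_half_up(phys.ssa_cm2_per_g, 1),
        })
    return pd.DataFrame(rows)
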