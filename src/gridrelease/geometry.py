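"""Geometry and dose arithmetic for 3D-printed drug-loaded grid inlays.

The drug-loaded compartment of the implant is a rectilinear network of
square-section strands printed in alternating 0°/90° layers inside an
impermeable shell.  A design is named "strand width × pore size" (mm).
Strand-layers stack densely, so the vertical pitch between layers equals
the strand width and the pore in the z-direction (between two strands of
the same orientation) equals the strand width as well.

The drug-eluting surface area is computed assuming ideal square strand
cross-sections; faces in contact with the shell or with neighbouring
layers are excluded according to an explicit :class:`ContactConvention`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .exceptions import DomainError
from .units import mm2_to_cm2

#: Drug mass fraction of the printed material: 10 % target load in the
#: filament times the 88.58 % recovered relative content.
DEFAULT_DRUG_LOAD_FRACTION = 0.08858

_TOL = 1e-9


@dataclass(frozen=True)
class NetworkDesign:
    """Parametric description of one drug-loaded grid inlay."""

    name: str
    strand_width: float  # mm
    pore_size_xy: float  # mm
    footprint_x: float  # mm
    footprint_y: float  # mm
    height: float  # mm
    layer_height: float = 0.2  # mm, printed slice thickness
    pore_size_z: float | None = None  # mm; always equals strand_width
    shell_thickness: float = 1.2  # mm

    def __post_init__(self) -> None:
        for attr in ("strand_width", "pore_size_xy", "footprint_x",
                     "footprint_y", "height", "layer_height",
                     "shell_thickness"):
            if getattr(self, attr) <= 0:
                raise DomainError(f"{attr} must be > 0")
        if self.pore_size_z is None:
            object.__setattr__(self, "pore_size_z", self.strand_width)
        elif abs(self.pore_size_z - self.strand_width) > _TOL:
            raise DomainError("pore_size_z must equal strand_width")
        if not _is_multiple(self.strand_width, self.layer_height):
            raise DomainError("strand_width must be a multiple of layer_height")
        if not _is_multiple(self.height, self.strand_width):
            raise DomainError("height must be a multiple of strand_width")


@dataclass(frozen=True)
class ContactConvention:
    """Which strand faces are excluded from the drug-eluting area.

    The shell encloses the network, so strand parts in contact with it
    (end faces, the bottom layer, optionally the outer side faces of edge
    strands) and the crossing contacts between stacked layers can be
    removed from the exposed area.
    """

    crossing_contacts: bool = True
    bottom_faces: bool = True
    end_faces: bool = True
    outer_side_faces: bool = False


DEFAULT_CONVENTION = ContactConvention()
NO_EXCLUSIONS = ContactConvention(False, False, False, False)


@dataclass(frozen=True)
class InlayPhysical:
    """Measured and derived physical properties of one printed inlay."""

    design: NetworkDesign | None
    mass_mg: float
    drug_load_fraction: float
    dose_mg: float
    area_calc_cm2: float
    area_true_cm2: float
    ssa_cm2_per_g: float
    area_ratio: float
    mass_sd_mg: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("mass_mg", "dose_mg", "area_calc_cm2",
                     "area_true_cm2", "ssa_cm2_per_g", "area_ratio"):
            if getattr(self, attr) < 0:
                raise DomainError(f"{attr} must be >= 0")


def _is_multiple(value: float, base: float, tol: float = 1e-6) -> bool:
    ratio = value / base
    return abs(ratio - round(ratio)) <= tol


def strands_per_layer(length: float, strand_width: float, pore_size: float) -> int:
    """Largest number of strands fitting across ``length``.

    n strands of width w separated by pores of size p occupy
    n·w + (n−1)·p; the strands sit flush with both edges when equality
    holds.
    """
    if length <= 0 or strand_width <= 0 or pore_size <= 0:
        raise DomainError("all lengths must be > 0")
    if length + _TOL < strand_width:
        raise DomainError("length must be at least one strand width")
    n = math.floor((length + pore_size + _TOL) / (strand_width + pore_size))
    return max(n, 1)


def layer_count(height: float, strand_width: float) -> int:
    """Number of densely stacked, alternating-orientation strand-layers."""
    if height <= 0 or strand_width <= 0:
        raise DomainError("height and strand_width must be > 0")
    if not _is_multiple(height, strand_width):
        raise DomainError("height must be an integer multiple of strand_width")
    return round(height / strand_width)


def calc_surface_area(design: NetworkDesign,
                      convention: ContactConvention = DEFAULT_CONVENTION) -> float:
    """Calculated drug-eluting surface area of a grid inlay, cm².

    Sums the exposed faces of all square-section strand prisms and
    subtracts the contact faces selected by ``convention``:

    * ``crossing_contacts`` — at every crossing between two adjacent
      orthogonal layers a w×w patch is hidden on both strands;
    * ``bottom_faces`` — the bottom faces of the lowest layer rest on the
      shell;
    * ``end_faces`` — strand ends abut the shell wall;
    * ``outer_side_faces`` — the outward side faces of the two edge
      strands of every layer run along the shell wall.
    """
    w = design.strand_width
    layers = layer_count(design.height, design.strand_width)
    # orientation alternates; layer 0 strands run along x
    counts: list[int] = []
    lengths: list[float] = []
    for i in range(layers):
        if i % 2 == 0:
            counts.append(strands_per_layer(design.footprint_y, w, design.pore_size_xy))
            lengths.append(design.footprint_x)
        else:
            counts.append(strands_per_layer(design.footprint_x, w, design.pore_size_xy))
            lengths.append(design.footprint_y)

    area = 0.0  # mm²
    for i in range(layers):
        n, length = counts[i], lengths[i]
        area += n * (4.0 * w * length + 2.0 * w * w)
        if convention.end_faces:
            area -= n * 2.0 * w * w
        if convention.outer_side_faces:
            # one outward face per edge strand; a single strand faces the
            # shell on both sides, so two faces are hidden either way
            area -= 2.0 * w * length
    if convention.bottom_faces:
        area -= counts[0] * w * lengths[0]
    if convention.crossing_contacts:
        for i in range(layers - 1):
            area -= counts[i] * counts[i + 1] * 2.0 * w * w
    return mm2_to_cm2(area)


def dose_from_mass(mass_mg: float,
                   drug_load_fraction: float = DEFAULT_DRUG_LOAD_FRACTION) -> float:
    """Drug dose (mg) of an inlay from its mass and drug load fraction."""
    if mass_mg < 0:
        raise DomainError("mass must be >= 0")
    if not 0.0 <= drug_load_fraction <= 1.0:
        raise DomainError("drug_load_fraction must lie in [0, 1]")
    return mass_mg * drug_load_fraction


def specific_surface_area(area_true_cm2: float, mass_mg: float) -> float:
    """Specific surface area, cm² per gram of inlay."""
    if mass_mg <= 0:
        raise DomainError("mass must be > 0")
    if area_true_cm2 < 0:
        raise DomainError("area must be >= 0")
    return area_true_cm2 / (mass_mg / 1000.0)


def area_ratio(area_true_cm2: float, area_calc_cm2: float) -> float:
    """Measured over calculated drug-eluting surface area."""
    if area_calc_cm2 <= 0:
        raise DomainError("calculated area must be > 0")
    return area_true_cm2 / area_calc_cm2


def filament_surface_area(n_sections: int, diameter_mm: float,
                          length_cm: float, include_ends: bool = False) -> float:
    """Theoretical drug-eluting area (cm²) of cylindrical filament sections."""
    if n_sections <= 0 or diameter_mm <= 0 or length_cm <= 0:
        raise DomainError("all arguments must be > 0")
    d_cm = diameter_mm / 10.0
    area = n_sections * math.pi * d_cm * length_cm
    if include_ends:
        area += 2.0 * n_sections * math.pi * (d_cm / 2.0) ** 2
    return area


def characterize(mass_mg: float, area_true_cm2: float, area_calc_cm2: float,
                 drug_load_fraction: float = DEFAULT_DRUG_LOAD_FRACTION,
                 design: NetworkDesign | None = None,
                 mass_sd_mg: float = 0.0) -> InlayPhysical:
    """Derive dose, SSA and area ratio for one inlay from its measurements."""
    return InlayPhysical(
        design=design,
        mass_mg=mass_mg,
        mass_sd_mg=mass_sd_mg,
        drug_load_fraction=drug_load_fraction,
        dose_mg=dose_from_mass(mass_mg, drug_load_fraction),
        area_calc_cm2=area_calc_cm2,
        area_true_cm2=area_true_cm2,
        ssa_cm2_per_g=specific_surface_area(area_true_cm2, mass_mg),
        area_ratio=area_ratio(area_true_cm2, area_calc_cm2),
    )


def with_convention(convention: ContactConvention, **flags: bool) -> ContactConvention:
    """Return a copy of ``convention`` with the given exclusion flags changed."""
    return replace(convention, **flags)
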