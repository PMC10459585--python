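"""Mass-balance reconstruction of cumulative release from sampling records.

Long-term dissolution runs sample the vessel repeatedly: small aliquots
are withdrawn (and not replaced), and at sampling intervals of 12 h or
more the entire medium is exchanged to maintain sink conditions, with
50 mL refills on weekdays and 75 mL over weekends.  Released drug partly
degrades into an impurity with a comparable detector response, so the
effective concentration is the sum of parent and degradant signals.

The cumulative released mass at event k is the drug currently in the
vessel plus everything permanently removed at earlier events:

    M_k = C_k · V_k  +  Σ_{j<k} C_j · (V_j if full change else aliquot_j)

Between-sample concentrations are never extrapolated; only measured
event concentrations enter the balance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DomainError, FormatError
from .units import conc_vol_to_mass_mg, hours_to_days, NG_PER_MG

#: Drug solubility in the dissolution medium at 37 °C, mg/L.
DEFAULT_SOLUBILITY_MG_L = 20.27
#: Concentration may reach this fraction of solubility under sink conditions.
DEFAULT_SINK_FRACTION = 0.30


@dataclass(frozen=True)
class SamplingEvent:
    """One sampling record of a dissolution run."""

    time_h: float
    volume_before_ml: float
    aliquot_ml: float
    full_change: bool
    refill_ml: float
    conc_parent_mg_l: float
    conc_degradant_mg_l: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_before_ml <= 0:
            raise DomainError("vessel volume must be > 0")
        if not 0.0 <= self.aliquot_ml <= self.volume_before_ml:
            raise DomainError("aliquot must lie in [0, vessel volume]")
        if self.conc_parent_mg_l < 0 or self.conc_degradant_mg_l < 0:
            raise DomainError("concentrations must be >= 0")

    @property
    def conc_effective_mg_l(self) -> float:
        return effective_concentration(self.conc_parent_mg_l, self.conc_degradant_mg_l)

    @property
    def removed_mass_mg(self) -> float:
        """Drug mass permanently removed from the vessel at this event."""
        removed_volume = self.volume_before_ml if self.full_change else self.aliquot_ml
        return conc_vol_to_mass_mg(self.conc_effective_mg_l, removed_volume)


@dataclass
class ReleaseProfile:
    """Reconstructed cumulative and relative release time series."""

    unit_id: str
    times_d: np.ndarray
    cumulative_mg: np.ndarray
    dose_mg: float
    exceeds_dose: bool = False  # content/recovery inconsistency warning

    def __post_init__(self) -> None:
        self.times_d = np.asarray(self.times_d, dtype=float)
        self.cumulative_mg = np.asarray(self.cumulative_mg, dtype=float)
        if self.times_d.shape != self.cumulative_mg.shape:
            raise FormatError("times and cumulative mass must align")
        if self.dose_mg <= 0:
            raise DomainError("dose must be > 0")

    @property
    def relative_release(self) -> np.ndarray:
        """Fraction of dose released, M_t / M_inf."""
        return self.cumulative_mg / self.dose_mg

    def rescaled(self, dose_mg: float) -> "ReleaseProfile":
        """Same cumulative data expressed against a different total content."""
        return ReleaseProfile(self.unit_id, self.times_d.copy(),
                              self.cumulative_mg.copy(), dose_mg)


@dataclass(frozen=True)
class PlateauResult:
    """Outcome of a plateau search; ``found`` is False when none exists."""

    found: bool
    total_mg: float | None
    window: int
    relative_spread: float


def effective_concentration(conc_parent_mg_l: float,
                            conc_degradant_mg_l: float) -> float:
    """Total drug-derived concentration, assuming equal detector response."""
    if conc_parent_mg_l < 0 or conc_degradant_mg_l < 0:
        raise DomainError("concentrations must be >= 0")
    return conc_parent_mg_l + conc_degradant_mg_l


def cumulative_release(events: list[SamplingEvent], dose_mg: float,
                       unit_id: str = "unit") -> ReleaseProfile:
    """Reconstruct the cumulative release profile from sampling records."""
    if dose_mg <= 0:
        raise DomainError("dose must be > 0")
    if not events:
        raise FormatError("no sampling events")
    times = np.array([e.time_h for e in events], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise FormatError("event times must be strictly increasing")

    cumulative = np.empty(len(events))
    removed_so_far = 0.0
    for k, event in enumerate(events):
        in_vessel = conc_vol_to_mass_mg(event.conc_effective_mg_l,
                                        event.volume_before_ml)
        cumulative[k] = in_vessel + removed_so_far
        removed_so_far += event.removed_mass_mg

    profile = ReleaseProfile(unit_id, hours_to_days(times), cumulative, dose_mg)
    if np.any(profile.cumulative_mg > dose_mg * (1 + 1e-9)):
        profile.exceeds_dose = True
    return profile


def daily_rate(profile: ReleaseProfile, reference_volume_ml: float = 50.0) -> np.ndarray:
    """Daily released mass per reference volume, ng·mL⁻¹·d⁻¹.

    The cumulative curve is linearly interpolated onto a daily grid; first
    differences give the per-day released mass, normalized to the assumed
    synovial volume (default 50 mL).
    """
    if reference_volume_ml <= 0:
        raise DomainError("reference volume must be > 0")
    if profile.times_d.size < 2:
        raise DomainError("profile must contain at least two points")
    n_days = int(np.floor(profile.times_d[-1]))
    if n_days < 1:
        raise DomainError("profile must span at least one day")
    grid = np.arange(0, n_days + 1, dtype=float)
    m = np.interp(grid, np.concatenate([[0.0], profile.times_d]),
                  np.concatenate([[0.0], profile.cumulative_mg]))
    return np.diff(m) * NG_PER_MG / reference_volume_ml


def sink_check(conc_mg_l: float, solubility_mg_l: float = DEFAULT_SOLUBILITY_MG_L,
               sink_fraction: float = DEFAULT_SINK_FRACTION) -> bool:
    """True when the concentration respects the sink-condition bound."""
    if solubility_mg_l <= 0:
        raise DomainError("solubility must be > 0")
    if not 0.0 < sink_fraction <= 1.0:
        raise DomainError("sink_fraction must lie in (0, 1]")
    return conc_mg_l <= sink_fraction * solubility_mg_l * (1 + 1e-12)


def plateau_total(profile: ReleaseProfile, window: int = 3,
                  tolerance: float = 0.01) -> PlateauResult:
    """Total drug content from the terminal plateau of a profile.

    Used for runs reaching complete dissolution (e.g. the crystal
    suspension), where the plateau mean is taken as the total content
    because removal of undissolved material during sampling cannot be
    excluded.
    """
    if window < 2:
        raise DomainError("window must be >= 2")
    if profile.times_d.size < window:
        raise DomainError("profile shorter than the plateau window")
    tail = profile.cumulative_mg[-window:]
    mean = float(np.mean(tail))
    spread = float((np.max(tail) - np.min(tail)) / mean) if mean > 0 else np.inf
    if spread <= tolerance:
        return PlateauResult(True, mean, window, spread)
    return PlateauResult(False, None, window, spread)


# ---------------------------------------------------------------------------
# CSV interfaces

EVENT_COLUMNS = ["unit_id", "time_h", "volume_before_mL", "aliquot_mL",
                 "full_change", "refill_mL", "conc_parent_mg_L",
                 "conc_degradant_mg_L"]

PROFILE_COLUMNS = ["unit_id", "time_d", "cumulative_mg", "relative_release"]


def read_events_csv(path: str | Path) -> dict[str, list[SamplingEvent]]:
    """Read sampling records; returns events grouped by unit id."""
    path = Path(path)
    units: dict[str, list[SamplingEvent]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(EVENT_COLUMNS) - set(reader.fieldnames):
            missing = set(EVENT_COLUMNS) - set(reader.fieldnames or [])
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                event = SamplingEvent(
                    time_h=float(row["time_h"]),
                    volume_before_ml=float(row["volume_before_mL"]),
                    aliquot_ml=float(row["aliquot_mL"]),
                    full_change=bool(int(row["full_change"])),
                    refill_ml=float(row["refill_mL"]),
                    conc_parent_mg_l=float(row["conc_parent_mg_L"]),
                    conc_degradant_mg_l=float(row["conc_degradant_mg_L"]),
                )
            except (ValueError, DomainError) as exc:
                raise FormatError(f"{path}: row {i}: {exc}") from exc
            units.setdefault(row["unit_id"], []).append(event)
    return units


def write_events_csv(path: str | Path, units: dict[str, list[SamplingEvent]]) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_COLUMNS)
        for unit_id, events in units.items():
            for e in events:
                writer.writerow([unit_id, f"{e.time_h:.6g}",
                                 f"{e.volume_before_ml:.6g}", f"{e.aliquot_ml:.6g}",
                                 int(e.full_change), f"{e.refill_ml:.6g}",
                                 repr(float(e.conc_parent_mg_l)),
                                 repr(float(e.conc_degradant_mg_l))])


def write_profile_csv(path: str | Path, profile: ReleaseProfile) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PROFILE_COLUMNS)
        for t, m, r in zip(profile.times_d, profile.cumulative_mg,
                           profile.relative_release):
            writer.writerow([profile.unit_id, f"{t:.6g}", repr(float(m)), repr(float(r))])


def read_profile_csv(path: str | Path, dose_mg: float | None = None) -> ReleaseProfile:
    """Read a release profile; the dose is recovered from the relative column
    unless given explicitly."""
    path = Path(path)
    times, masses, rels, unit = [], [], [], None
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(PROFILE_COLUMNS) - set(reader.fieldnames):
            raise FormatError(f"{path}: expected columns {PROFILE_COLUMNS}")
        for row in reader:
            unit = row["unit_id"]
            times.append(float(row["time_d"]))
            masses.append(float(row["cumulative_mg"]))
            rels.append(float(row["relative_release"]))
    if not times:
        raise FormatError(f"{path}: empty profile")
    if dose_mg is None:
        idx = int(np.argmax(masses))
        if rels[idx] <= 0:
            raise FormatError(f"{path}: cannot infer dose from all-zero release")
        dose_mg = masses[idx] / rels[idx]
    return ReleaseProfile(unit or "unit", np.array(times), np.array(masses), dose_mg)
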