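"""Synthetic dissolution studies with ground truth.

The study's dissolution curves exist only as figures, so every pipeline
stage is exercised against simulated data instead.  The generator
produces (a) deterministic ground-truth release curves, and (b) full
sampling-protocol records — aliquots, complete media changes, weekday
50 mL / weekend 75 mL vessel volumes, partial degradation of the parent
drug into an impurity, an overall measurement recovery below one, and
multiplicative lognormal noise on concentrations — that feed directly
into :mod:`gridrelease.accounting`.

Truth curves for the implant regime follow a burst + power-law blend

    M_t = dose · [ b·(1 − e^(−t/τ_b)) + (1 − b)·k·tⁿ ],   capped at dose,

with burst time constant τ_b = 1.5 d (a saturating burst over roughly
the first five days) and anomalous-transport exponents n.  Fixture
parameters mirror the nine-implant study set: published doses, exponents
clipped into [0.58, 0.70], burst fractions of 10–25 % of dose, and
90-day release fractions interpolated in specific surface area between
the slowest (19.7 % of dose) and fastest (75.4 %) implants, capped at
80 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .accounting import ReleaseProfile, SamplingEvent
from .designs import STUDY_IMPLANTS, get_implant
from .exceptions import DomainError

BURST_TAU_D = 1.5
#: Fixture defaults for measurement imperfections.
DEFAULT_NOISE_SIGMA = 0.02
DEFAULT_DEGRADANT_FRACTION = 0.03
DEFAULT_RECOVERY = 0.965

_TRUTH_MODELS = ("kp", "higuchi", "weibull", "peppas_sahlin", "burst_plus_kp")


@dataclass(frozen=True)
class ProtocolStep:
    """Skeleton of one sampling event: when and how the vessel is handled."""

    time_h: float
    aliquot_ml: float
    full_change: bool
    refill_ml: float


@dataclass(frozen=True)
class Protocol:
    initial_volume_ml: float
    steps: tuple[ProtocolStep, ...]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed to simulate one dissolution run."""

    unit_id: str
    truth_model: str
    truth_params: dict[str, float]
    dose_mg: float
    protocol: Protocol
    seed: int
    burst_fraction: float = 0.0
    burst_tau_d: float = BURST_TAU_D
    noise_sigma: float = 0.0
    degradant_fraction: float = 0.0
    recovery: float = 1.0

    def __post_init__(self) -> None:
        if self.truth_model not in _TRUTH_MODELS:
            raise DomainError(f"unknown truth model {self.truth_model!r}")
        if self.dose_mg <= 0:
            raise DomainError("dose must be > 0")
        for attr in ("burst_fraction", "degradant_fraction"):
            if not 0.0 <= getattr(self, attr) <= 1.0:
                raise DomainError(f"{attr} must lie in [0, 1]")
        if not 0.0 < self.recovery <= 1.0:
            raise DomainError("recovery must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise DomainError("an explicit integer seed is required")


def _relative_truth(spec: SimulationSpec, t: np.ndarray) -> np.ndarray:
    p = spec.truth_params
    if spec.truth_model == "kp":
        return p["k"] * t ** p["n"]
    if spec.truth_model == "higuchi":
        # either a direct relative rate a, or dk·area against the dose
        a = p["a"] if "a" in p else p["dk"] * p["area_cm2"] / spec.dose_mg
        return a * np.sqrt(t)
    if spec.truth_model == "weibull":
        return 1.0 - np.exp(-p["a"] * t ** p["b"])
    if spec.truth_model == "peppas_sahlin":
        return p["k1"] * t ** p["m"] + p["k2"] * t ** (2 * p["m"])
    b = spec.burst_fraction
    return (b * (1.0 - np.exp(-t / spec.burst_tau_d))
            + (1.0 - b) * p["k"] * t ** p["n"])


def true_release(spec: SimulationSpec, times_d: np.ndarray) -> ReleaseProfile:
    """Deterministic ground-truth cumulative release at the given times."""
    t = np.asarray(times_d, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be >= 0")
    rel = np.minimum(_relative_truth(spec, t), 1.0)
    return ReleaseProfile(spec.unit_id, t, rel * spec.dose_mg, spec.dose_mg)


def simulate_study(spec: SimulationSpec) -> list[SamplingEvent]:
    """Walk the sampling protocol over the ground-truth curve.

    The physical mass balance (what is actually removed from the vessel)
    uses the true concentration; recovery, the parent/degradant split and
    the seeded multiplicative lognormal noise affect only the recorded
    concentrations.  The lognormal factors are mean-one
    (exp(σZ − σ²/2)) so noise does not bias the reconstruction.
    """
    rng = np.random.default_rng(spec.seed)
    truth = true_release(spec, np.array([s.time_h / 24.0 for s in spec.protocol.steps]))
    volume = spec.protocol.initial_volume_ml
    removed_total = 0.0
    events: list[SamplingEvent] = []
    for k, step in enumerate(spec.protocol.steps):
        in_vessel_mg = truth.cumulative_mg[k] - removed_total
        conc_true = in_vessel_mg / volume * 1000.0  # mg/L
        if spec.noise_sigma > 0:
            factor = math.exp(rng.normal(0.0, spec.noise_sigma)
                              - spec.noise_sigma**2 / 2.0)
        else:
            rng.normal()  # keep the stream aligned across sigma settings
            factor = 1.0
        conc_meas = conc_true * spec.recovery * factor
        events.append(SamplingEvent(
            time_h=step.time_h,
            volume_before_ml=volume,
            aliquot_ml=step.aliquot_ml,
            full_change=step.full_change,
            refill_ml=step.refill_ml,
            conc_parent_mg_l=conc_meas * (1.0 - spec.degradant_fraction),
            conc_degradant_mg_l=conc_meas * spec.degradant_fraction,
        ))
        removed_volume = volume if step.full_change else step.aliquot_ml
        removed_total += conc_true * removed_volume / 1000.0
        volume = step.refill_ml
    return events


# ---------------------------------------------------------------------------
# Sampling protocols

def implant_protocol(duration_d: int = 90, start_weekday: int = 0,
                     weekday_volume_ml: float = 50.0,
                     weekend_volume_ml: float = 75.0,
                     aliquot_ml: float = 5.0) -> Protocol:
    """Long-term protocol: dense day-one sampling, daily weekday changes
    for the first ten days, then twice-weekly (Mon/Thu) media changes.

    Aliquots less than 12 h apart are withdrawn without replacement; any
    interval of 12 h or more ends with a complete media change.  The
    refill volume is raised to the weekend level whenever the next
    sampling is more than two days away.
    """
    sample_days: list[int] = []
    for d in range(2, 11):
        if (start_weekday + d) % 7 not in (5, 6):
            sample_days.append(d)
    for d in range(11, duration_d + 1):
        if (start_weekday + d) % 7 in (0, 3):
            sample_days.append(d)
    times_h: list[tuple[float, bool]] = [(2.0, False), (4.0, False),
                                         (8.0, False), (12.0, True), (24.0, True)]
    times_h += [(day * 24.0, True) for day in sorted(sample_days)]

    def spans_weekend(t_h: float, t_next_h: float) -> bool:
        first = math.floor(t_h / 24.0)
        last = math.ceil(t_next_h / 24.0)
        return any((start_weekday + day) % 7 == 5 for day in range(first, last))

    steps: list[ProtocolStep] = []
    volume = weekday_volume_ml
    for i, (t_h, full) in enumerate(times_h):
        if full:
            if i + 1 < len(times_h) and spans_weekend(t_h, times_h[i + 1][0]):
                refill = weekend_volume_ml
            else:
                refill = weekday_volume_ml
        else:
            refill = volume - aliquot_ml  # aliquots are not replaced
        steps.append(ProtocolStep(t_h, aliquot_ml, full, refill))
        volume = refill
    return Protocol(weekday_volume_ml, tuple(steps))


def suspension_protocol(volume_ml: float = 1000.0, sample_ml: float = 0.8,
                        times_min: tuple[float, ...] = (5, 10, 15, 20, 30, 45,
                                                        60, 90, 120, 180)) -> Protocol:
    """Fixed-volume protocol for the fast-dissolving crystal suspension:
    small samples replaced with fresh medium, vessel volume constant."""
    steps = tuple(ProtocolStep(m / 60.0, sample_ml, False, volume_ml)
                  for m in times_min)
    return Protocol(volume_ml, steps)


# ---------------------------------------------------------------------------
# Fixture studies

#: Diffusional exponents of the nine implants, clipped into the
#: anomalous-transport range [0.58, 0.70] reported for the study set.
STUDY_EXPONENTS: dict[str, float] = {
    "0.4 × 0.4": 0.70, "0.4 × 0.8": 0.69, "0.4 × 1.2": 0.58,
    "0.8 × 0.4": 0.66, "0.8 × 0.8": 0.68, "0.8 × 1.2": 0.60,
    "1.2 × 0.4": 0.65, "1.2 × 0.8": 0.59, "1.2 × 1.2": 0.58,
}

#: Anchors for the 90-day release fraction: slowest and fastest implants.
_REL90_ANCHORS = {"ssa_lo": 19.9, "rel_lo": 8.58 / 43.5,
                  "ssa_hi": 62.6, "rel_hi": 21.93 / 29.1}
_REL90_CAP = 0.80
_BURST_RANGE = (0.10, 0.25)


def _implant_truth(name: str) -> tuple[float, float, float, float]:
    """(burst_fraction, n, k, rel90) for one study implant."""
    rec = get_implant(name)
    a = _REL90_ANCHORS
    frac = (rec.ssa_ref_cm2_per_g - a["ssa_lo"]) / (a["ssa_hi"] - a["ssa_lo"])
    rel90 = min(a["rel_lo"] + (a["rel_hi"] - a["rel_lo"]) * frac, _REL90_CAP)
    ssa_all = [r.ssa_ref_cm2_per_g for r in STUDY_IMPLANTS]
    burst = (_BURST_RANGE[0] + (_BURST_RANGE[1] - _BURST_RANGE[0])
             * (rec.ssa_ref_cm2_per_g - min(ssa_all)) / (max(ssa_all) - min(ssa_all)))
    n = STUDY_EXPONENTS[name]
    k = (rel90 - burst * (1.0 - math.exp(-90.0 / BURST_TAU_D))) / ((1.0 - burst) * 90.0**n)
    return burst, n, k, rel90


def implant_spec(name: str, seed: int,
                 noise_sigma: float = DEFAULT_NOISE_SIGMA,
                 degradant_fraction: float = DEFAULT_DEGRADANT_FRACTION,
                 recovery: float = DEFAULT_RECOVERY,
                 duration_d: int = 90,
                 burst_fraction: float | None = None) -> SimulationSpec:
    """Simulation spec for one of the nine study implants.

    ``burst_fraction=None`` uses the fixture default (10–25 % of dose by
    SSA); pass 0.0 for the pure anomalous power-law regime, in which the
    same implant releases the same 90-day amount without a burst phase.
    """
    rec = get_implant(name)
    burst, n, _, rel90 = _implant_truth(name)
    if burst_fraction is not None:
        burst = burst_fraction
    k = (rel90 - burst * (1.0 - math.exp(-90.0 / BURST_TAU_D))) / ((1.0 - burst) * 90.0**n)
    return SimulationSpec(
        unit_id=name, truth_model="burst_plus_kp",
        truth_params={"k": k, "n": n}, dose_mg=rec.dose_ref_mg,
        protocol=implant_protocol(duration_d=duration_d), seed=seed,
        burst_fraction=burst, noise_sigma=noise_sigma,
        degradant_fraction=degradant_fraction, recovery=recovery,
    )


def filament_spec(seed: int, noise_sigma: float = DEFAULT_NOISE_SIGMA,
                  degradant_fraction: float = DEFAULT_DEGRADANT_FRACTION,
                  recovery: float = DEFAULT_RECOVERY) -> SimulationSpec:
    """Three 2.5 cm filament sections in a basket: ~20 mg dose, 4.12 cm²
    theoretical eluting area, 8.97 mg released over 90 d."""
    burst, n, rel90 = 0.10, 0.60, 8.97 / 20.0
    k = (rel90 - burst * (1.0 - math.exp(-90.0 / BURST_TAU_D))) / ((1.0 - burst) * 90.0**n)
    return SimulationSpec(
        unit_id="filament", truth_model="burst_plus_kp",
        truth_params={"k": k, "n": n}, dose_mg=20.0,
        protocol=implant_protocol(), seed=seed, burst_fraction=burst,
        noise_sigma=noise_sigma, degradant_fraction=degradant_fraction,
        recovery=recovery,
    )


def suspension_spec(seed: int, noise_sigma: float = DEFAULT_NOISE_SIGMA) -> SimulationSpec:
    """6 mg crystal suspension in 1000 mL, completely dissolved within
    100 min (first-order truth, ≥ 99 % by then)."""
    return SimulationSpec(
        unit_id="suspension", truth_model="weibull",
        truth_params={"a": 80.0, "b": 1.0}, dose_mg=6.0,
        protocol=suspension_protocol(), seed=seed, noise_sigma=noise_sigma,
    )


def fixture_study(preset: str, seed: int,
                  noise_sigma: float = DEFAULT_NOISE_SIGMA,
                  degradant_fraction: float = DEFAULT_DEGRADANT_FRACTION,
                  recovery: float = DEFAULT_RECOVERY
                  ) -> tuple[list[SimulationSpec], dict[str, list[SamplingEvent]], dict]:
    """Ready-made study bundle: specs, simulated records and a manifest.

    Presets: ``nine_implants`` (the full study set), ``filament``,
    ``suspension``.  Each unit draws its noise from an independent
    seeded stream derived from ``seed``.
    """
    if preset == "nine_implants":
        specs = [implant_spec(rec.name, seed=seed + i, noise_sigma=noise_sigma,
                              degradant_fraction=degradant_fraction, recovery=recovery)
                 for i, rec in enumerate(STUDY_IMPLANTS)]
    elif preset == "filament":
        specs = [filament_spec(seed=seed, noise_sigma=noise_sigma,
                               degradant_fraction=degradant_fraction,
                               recovery=recovery)]
    elif preset == "suspension":
        specs = [suspension_spec(seed=seed, noise_sigma=noise_sigma)]
    else:
        raise DomainError(f"unknown preset {preset!r}")
    records = {spec.unit_id: simulate_study(spec) for spec in specs}
    manifest = {
        "preset": preset, "seed": seed,
        "units": [{
            "unit_id": s.unit_id, "truth_model": s.truth_model,
            "truth_params": dict(s.truth_params), "dose_mg": s.dose_mg,
            "burst_fraction": s.burst_fraction, "burst_tau_d": s.burst_tau_d,
            "noise_sigma": s.noise_sigma,
            "degradant_fraction": s.degradant_fraction,
            "recovery": s.recovery, "seed": s.seed,
        } for s in specs],
    }
    return specs, records, manifest
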