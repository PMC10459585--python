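"""Higuchi-based release prediction and RMSEP scoring.

Two prediction routes:

* **D_k transfer** — the lumped Higuchi constant fitted on one implant is
  combined with the measured drug-eluting surface area of another implant
  of the same strand width: ``M_t = D_k · A · √t``.  Implants with a
  0.4 mm pore size are excluded by default (pore clogging by the swelling
  pore former changes the kinetics there).
* **Early-data extrapolation** — relative release (%) observed during the
  first 15 days is regressed on √t and the line extrapolated over the
  remaining horizon, evaluated only while observed release stays below
  60 %.  The burst phase (first 5 days by default) is excluded from the
  training regression: the additive burst is not square-root-of-time
  behaviour and would bias the extrapolated slope.

Predictions are scored with the root mean square error of prediction on
relative release in percent of dose,

    RMSEP = sqrt( Σ (y_i − ŷ_i)² / n ),

with n counting evaluation points only.  RMSEP < 5 % is considered an
acceptable prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .accounting import ReleaseProfile
from .exceptions import DomainError, InsufficientDataError
from .kinetics import KineticsFit, _ols

DEFAULT_RMSEP_THRESHOLD_PCT = 5.0
DEFAULT_CAP = 0.60
DEFAULT_TRAINING_HORIZON_D = 15.0
#: Training points earlier than this are dropped from the √t regression
#: (burst-phase exclusion); set to 0 to train on the full early window.
DEFAULT_BURST_EXCLUSION_D = 5.0
#: Pore size (mm) excluded from D_k transfer by default.
DEFAULT_PORE_EXCLUSION_MM = 0.4


@dataclass(frozen=True)
class PredictionResult:
    """A predicted release curve with its provenance and RMSEP."""

    method: str  # "dk_transfer" | "early_extrapolation"
    source_unit: str | None
    target_unit: str
    predicted: ReleaseProfile
    rmsep_pct: float
    training_horizon_d: float | None = None
    regression_r2: float | None = None

    def __post_init__(self) -> None:
        if self.rmsep_pct < 0:
            raise DomainError("RMSEP must be >= 0")


def predict_from_dk(dk: float, area_cm2: float, times_d: np.ndarray,
                    dose_mg: float, intercept_q: float = 0.0,
                    unit_id: str = "predicted") -> ReleaseProfile:
    """Square-root-of-time release curve from a lumped Higuchi constant.

    ``M_t = (D_k·√t + intercept_q)·A``; the optional intercept (in the
    same mg/cm² units as Q) reproduces a fitted line that was not forced
    through the origin.
    """
    if dk <= 0 or area_cm2 <= 0:
        raise DomainError("D_k and area must be > 0")
    t = np.asarray(times_d, dtype=float)
    if np.any(t < 0):
        raise DomainError("times must be >= 0")
    mass = (dk * np.sqrt(t) + intercept_q) * area_cm2
    return ReleaseProfile(unit_id, t, mass, dose_mg)


def rmsep(observed: ReleaseProfile, predicted: ReleaseProfile) -> float:
    """RMSEP between two profiles on an identical time grid, in % of dose."""
    if observed.times_d.shape != predicted.times_d.shape or \
            not np.array_equal(observed.times_d, predicted.times_d):
        raise DomainError("observed and predicted profiles must share their time grid")
    y = observed.relative_release * 100.0
    yhat = predicted.relative_release * 100.0
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def assess(rmsep_pct: float,
           threshold_pct: float = DEFAULT_RMSEP_THRESHOLD_PCT) -> bool:
    """True when the prediction error is strictly below the threshold."""
    if rmsep_pct < 0:
        raise DomainError("RMSEP must be >= 0")
    return rmsep_pct < threshold_pct


def dk_transfer(donor_fit: KineticsFit, target: ReleaseProfile,
                target_area_cm2: float, source_unit: str | None = None,
                include_intercept: bool = False) -> PredictionResult:
    """Predict a target implant's release from a donor's fitted D_k.

    Evaluated on all observed time points of the target profile.
    """
    if donor_fit.model != "higuchi":
        raise DomainError("donor fit must be a Higuchi fit")
    intercept = donor_fit.params.get("intercept", 0.0) if include_intercept else 0.0
    predicted = predict_from_dk(donor_fit.params["dk"], target_area_cm2,
                                target.times_d, target.dose_mg,
                                intercept_q=intercept,
                                unit_id=f"{target.unit_id} (predicted)")
    return PredictionResult(
        method="dk_transfer",
        source_unit=source_unit if source_unit is not None else donor_fit.unit_id,
        target_unit=target.unit_id,
        predicted=predicted,
        rmsep_pct=rmsep(target, predicted),
    )


def predict_from_early(profile: ReleaseProfile,
                       training_horizon_d: float = DEFAULT_TRAINING_HORIZON_D,
                       horizon_d: float = 90.0,
                       cap: float = DEFAULT_CAP,
                       burst_exclusion_d: float = DEFAULT_BURST_EXCLUSION_D
                       ) -> PredictionResult:
    """Extrapolate a release curve from its early observations.

    Relative release (%) with ``burst_exclusion_d < t ≤ training_horizon_d``
    and release ≤ cap is regressed on √t; the line predicts release at
    the observed post-training times up to ``horizon_d``, evaluated only
    where the observed release is still ≤ cap.
    """
    if not 0.0 < cap <= 1.0:
        raise DomainError("cap must lie in (0, 1]")
    if training_horizon_d >= horizon_d:
        raise DomainError("training horizon must precede the evaluation horizon")
    t, rel = profile.times_d, profile.relative_release
    train = (t > burst_exclusion_d) & (t <= training_horizon_d) & (rel <= cap)
    if np.count_nonzero(train) < 3:
        raise InsufficientDataError(
            f"{profile.unit_id}: {np.count_nonzero(train)} training points "
            f"in ({burst_exclusion_d}, {training_horizon_d}] d")
    slope, intercept, r2 = _ols(np.sqrt(t[train]), rel[train] * 100.0)

    evaluate = (t > training_horizon_d) & (t <= horizon_d) & (rel <= cap)
    if np.count_nonzero(evaluate) == 0:
        raise InsufficientDataError(
            f"{profile.unit_id}: no evaluation points past {training_horizon_d} d")
    t_eval = t[evaluate]
    pred_rel = (intercept + slope * np.sqrt(t_eval)) / 100.0
    predicted = ReleaseProfile(f"{profile.unit_id} (predicted)", t_eval,
                               pred_rel * profile.dose_mg, profile.dose_mg)
    observed = ReleaseProfile(profile.unit_id, t_eval,
                              profile.cumulative_mg[evaluate], profile.dose_mg)
    return PredictionResult(
        method="early_extrapolation",
        source_unit=None,
        target_unit=profile.unit_id,
        predicted=predicted,
        rmsep_pct=rmsep(observed, predicted),
        training_horizon_d=training_horizon_d,
        regression_r2=r2,
    )
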