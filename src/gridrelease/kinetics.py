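"""Release-kinetics model fitting.

Four models are supported, all on relative release ``r = M_t / M_inf``
with time in days:

* power law (Korsmeyer–Peppas): ``r = k·tⁿ``, fitted as ordinary least
  squares of log10(r) on log10(t); the slope is the diffusional exponent
  n (0.45 = Fickian square-root kinetics and 1.0 = zero order for
  cylinders), the intercept gives k.
* Higuchi: released mass per drug-eluting area ``Q = M_t / A`` regressed
  on √t; the slope is the lumped constant D_k (mg·cm⁻²·d⁻⁰·⁵), which
  absorbs diffusivity, porosity, tortuosity and the loading/solubility
  terms of the full Higuchi expression.  The intercept is kept free
  because burst release biases a through-origin fit.
* Peppas–Sahlin: ``r = k1·t^m + k2·t^(2m)`` (diffusion + relaxation).
* Weibull: ``r = 1 − exp(−a·t^b)``.

The nonlinear models are fitted with the Levenberg–Marquardt algorithm
(lmfit).  Fits use only points whose relative release lies strictly
inside the fitting window — by default 5–60 %, below which the burst
dominates and above which the underlying model assumptions fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model

from .accounting import ReleaseProfile
from .exceptions import DomainError, InsufficientDataError

DEFAULT_WINDOW = (0.05, 0.60)
#: Diffusional-exponent thresholds for cylindrical geometry.
N_FICKIAN = 0.45
N_CASE_II = 1.0

GEOMETRY_CAVEAT = (
    "exponent thresholds (0.45 Fickian, 1.0 case II) hold for cylindrical "
    "samples; grid networks with unidirectional release deviate from them"
)


@dataclass(frozen=True)
class KineticsFit:
    """Fitted parameters and goodness of fit for one model on one profile."""

    model: str
    params: dict[str, float]
    window: tuple[float, float]
    r_squared: float
    n_points: int
    unit_id: str = ""
    converged: bool = True
    message: str = ""


@dataclass(frozen=True)
class MechanismClass:
    """Release-mechanism label derived from the diffusional exponent."""

    label: str
    n_value: float
    geometry_caveat: str = GEOMETRY_CAVEAT


def _window_points(profile: ReleaseProfile, window: tuple[float, float],
                   require_positive_time: bool = True):
    lower, upper = window
    if not 0.0 <= lower < upper <= 1.0:
        raise DomainError("window must satisfy 0 <= lower < upper <= 1")
    rel = profile.relative_release
    mask = (rel > lower) & (rel < upper)
    if require_positive_time:
        mask &= profile.times_d > 0
    return profile.times_d[mask], rel[mask]


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, r_squared)."""
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (intercept + slope * x)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def kp_fit(profile: ReleaseProfile,
           window: tuple[float, float] = DEFAULT_WINDOW) -> KineticsFit:
    """Power-law fit on the log–log linearization.

    log10(M_t/M_inf) = log10(k) + n·log10(t); the slope is the diffusional
    exponent n.
    """
    t, rel = _window_points(profile, window)
    if t.size < 3:
        raise InsufficientDataError(
            f"{profile.unit_id}: only {t.size} points inside window {window}")
    slope, intercept, r2 = _ols(np.log10(t), np.log10(rel))
    return KineticsFit("korsmeyer_peppas", {"k": 10.0**intercept, "n": slope},
                       window, r2, int(t.size), profile.unit_id)


def classify_mechanism(n: float, tolerance: float = 0.02) -> MechanismClass:
    """Classify the transport mechanism from the diffusional exponent."""
    if not np.isfinite(n):
        raise DomainError("exponent must be finite")
    if abs(n - N_FICKIAN) <= tolerance:
        label = "fickian"
    elif abs(n - N_CASE_II) <= tolerance:
        label = "case_II"
    elif N_FICKIAN < n < N_CASE_II:
        label = "anomalous"
    elif n < N_FICKIAN:
        label = "sub_fickian"
    else:
        label = "super_case_II"
    return MechanismClass(label, n)


def higuchi_fit(profile: ReleaseProfile, area_cm2: float,
                window: tuple[float, float] = DEFAULT_WINDOW) -> KineticsFit:
    """Square-root-of-time fit of released mass per unit area.

    Q = M_t/A is regressed on √t (t in days); the slope is D_k in
    mg·cm⁻²·d⁻⁰·⁵ and a free intercept absorbs burst release.
    """
    if area_cm2 <= 0:
        raise DomainError("area must be > 0")
    t, rel = _window_points(profile, window, require_positive_time=False)
    if t.size < 3:
        raise InsufficientDataError(
            f"{profile.unit_id}: only {t.size} points inside window {window}")
    q = rel * profile.dose_mg / area_cm2
    slope, intercept, r2 = _ols(np.sqrt(t), q)
    return KineticsFit("higuchi", {"dk": slope, "intercept": intercept},
                       window, r2, int(t.size), profile.unit_id)


def _peppas_sahlin(t, k1, k2, m):
    return k1 * t**m + k2 * t ** (2 * m)


def _weibull(t, a, b):
    return 1.0 - np.exp(-a * t**b)


def _default_start(profile: ReleaseProfile, model: str,
                   window: tuple[float, float]) -> dict[str, float]:
    """Start values from a power-law pre-fit; fall back to generic ones."""
    try:
        pre = kp_fit(profile, window)
        k, n = pre.params["k"], min(max(pre.params["n"], 0.05), 0.99)
    except (InsufficientDataError, DomainError):
        k, n = 0.05, 0.5
    if model == "weibull":
        return {"a": max(k, 1e-6), "b": n}
    return {"k1": max(k, 1e-6), "k2": 1e-3, "m": n}


def nonlinear_fit(profile: ReleaseProfile, model: str,
                  window: tuple[float, float] = (0.0, 0.60),
                  start: dict[str, float] | None = None,
                  seed: int = 0) -> KineticsFit:
    """Levenberg–Marquardt fit of the Peppas–Sahlin or Weibull model.

    Fits relative release on data below the upper window bound.  On
    non-convergence a failure result carrying the last iterate is
    returned (``converged=False``); a seeded random restart is attempted
    first.
    """
    if model not in ("peppas_sahlin", "weibull"):
        raise DomainError(f"unknown nonlinear model {model!r}")
    t, rel = _window_points(profile, window)
    func = _peppas_sahlin if model == "peppas_sahlin" else _weibull
    n_free = 3 if model == "peppas_sahlin" else 2
    if t.size < n_free + 1:
        raise InsufficientDataError(
            f"{profile.unit_id}: {t.size} points cannot constrain {n_free} parameters")
    start = dict(start) if start else _default_start(profile, model, window)
    if any(not np.isfinite(v) for v in start.values()):
        raise DomainError("start values must be finite")

    lm = Model(func)
    params = lm.make_params(**start)
    if model == "peppas_sahlin":
        params["m"].set(min=1e-6, max=1.0)
        params["k1"].set(min=0.0)
    else:
        params["a"].set(min=1e-12)
        params["b"].set(min=1e-6)

    result = lm.fit(rel, params, t=t, method="leastsq")
    if not result.success:
        rng = np.random.default_rng(seed)
        jittered = {k: v * float(rng.uniform(0.5, 2.0)) for k, v in start.items()}
        retry = lm.fit(rel, lm.make_params(**jittered), t=t, method="leastsq")
        if retry.success:
            result = retry

    fitted = {name: float(p.value) for name, p in result.params.items()}
    ss_tot = float(np.sum((rel - np.mean(rel)) ** 2))
    r2 = 1.0 - float(np.sum(result.residual**2)) / ss_tot if ss_tot > 0 else 1.0
    return KineticsFit(model, fitted, window, r2, int(t.size), profile.unit_id,
                       converged=bool(result.success),
                       message="" if result.success else str(result.message))


def evaluate_model(model: str, params: dict[str, float], times_d: np.ndarray) -> np.ndarray:
    """Relative release predicted by a fitted model at the given times."""
    t = np.asarray(times_d, dtype=float)
    if model == "korsmeyer_peppas":
        return params["k"] * t ** params["n"]
    if model == "peppas_sahlin":
        return _peppas_sahlin(t, params["k1"], params["k2"], params["m"])
    if model == "weibull":
        return _weibull(t, params["a"], params["b"])
    raise DomainError(f"cannot evaluate model {model!r} on relative release")
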