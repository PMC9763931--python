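"""Logistic concentration–response fitting and reactivity components.

Dilator responses of cannulated vessels across agonist concentrations are
fit with the four-concentration logistic

    y = min + (max − min) / (1 + 10^(logEC50 − x))

where ``x`` is log10 agonist concentration, ``y`` the diameter change (μm),
``min``/``max`` its lower/upper bounds and logEC50 the half-maximal
concentration.  The fitted upper bound is the component value that enters
the index; the hypoxic response is a single challenge and passes through
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .model import (
    Agonist,
    Bed,
    Component,
    ComponentValue,
    DegenerateDataError,
    DoseResponseSeries,
    HypoxicChallenge,
    InsufficientDataError,
    LogisticFit,
)

log = logging.getLogger("vhi")

_AGONIST_COMPONENT = {
    Agonist.ACETYLCHOLINE: Component.ACH_DILATION,
    Agonist.NITROPRUSSIDE: Component.SNP_DILATION,
}

_N_RESTARTS = 5  # jittered restarts on poor convergence
_EC50_MARGIN = 2.0  # logEC50 search window beyond observed concentrations


@dataclass(frozen=True)
class LogisticModelParams:
    """Parameter triple of the logistic model (evaluates to (min+max)/2 at logEC50)."""

    min: float
    max: float
    log_ec50: float


def logistic_response(params: LogisticModelParams, x: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the logistic model at log10 concentration ``x``."""
    return params.min + (params.max - params.min) / (1.0 + 10.0 ** (params.log_ec50 - np.asarray(x)))


def _initial_guess(x: np.ndarray, y: np.ndarray) -> LogisticModelParams:
    lo, hi = float(np.min(y)), float(np.max(y))
    half = (lo + hi) / 2.0
    # concentration nearest the half-range crossing
    ec50 = float(x[np.argmin(np.abs(y - half))])
    return LogisticModelParams(lo, hi, ec50)


def fit_logistic(series: DoseResponseSeries) -> LogisticFit:
    """Least-squares fit of the logistic model to one concentration series.

    Uses analytic initial guesses and up to five jittered restarts; logEC50
    is constrained to the observed concentration range ± 2 log units so
    near-flat data cannot drive it to infinity.  A zero-variance series is
    uninformative and raises :class:`DegenerateDataError`.
    """
    x = np.asarray(series.log_conc, dtype=float)
    y = np.asarray(series.response_um, dtype=float)
    if len(np.unique(x)) < 4:
        raise InsufficientDataError(
            f"need >=4 distinct concentrations (animal {series.animal_id})")
    if np.ptp(y) == 0.0:
        raise DegenerateDataError(
            f"all responses equal ({y[0]:g} μm); logistic fit undefined "
            f"(animal {series.animal_id})")

    guess = _initial_guess(x, y)
    lo_ec, hi_ec = float(x.min()) - _EC50_MARGIN, float(x.max()) + _EC50_MARGIN
    span = max(np.ptp(y), 1.0)
    lower = [guess.min - 10 * span, guess.min - 10 * span, lo_ec]
    upper = [guess.max + 10 * span, guess.max + 10 * span, hi_ec]

    def residuals(p: np.ndarray) -> np.ndarray:
        return logistic_response(LogisticModelParams(*p), x) - y

    rng = np.random.default_rng(0)  # deterministic restart jitter
    best: Optional[np.ndarray] = None
    best_sse = np.inf
    p0 = np.array([guess.min, guess.max, np.clip(guess.log_ec50, lo_ec, hi_ec)])
    for attempt in range(_N_RESTARTS + 1):
        start = p0 if attempt == 0 else np.clip(
            p0 + rng.normal(0.0, [0.1 * span, 0.1 * span, 0.5]), lower, upper)
        try:
            sol = least_squares(residuals, start, bounds=(lower, upper), method="trf")
        except Exception:  # numerical failure on this start
            continue
        if sol.success and sol.cost * 2.0 < best_sse:
            best = sol.x
            best_sse = sol.cost * 2.0
        # an essentially perfect fit cannot be improved by restarting
        if best is not None and best_sse <= 1e-16 * max(1.0, float(y @ y)):
            break

    if best is None:
        return LogisticFit(float("nan"), float("nan"), float("nan"),
                           residual_sse=float(y.var() * len(y)), converged=False)
    mn, mx, ec = (float(v) for v in best)
    if mx < mn:  # canonical orientation: max is the upper bound
        mn, mx = mx, mn
    return LogisticFit(lower_bound_um=mn, upper_bound_um=mx, log_ec50=ec,
                       residual_sse=float(best_sse), converged=True)


def dilation_upper_bound(fit: LogisticFit, animal_id: str, bed: Bed,
                         agonist: Agonist) -> Optional[ComponentValue]:
    """Extract the fitted upper bound as the dilation component (μm).

    Returns ``None`` for an unconverged fit (component absent, logged).
    """
    if not fit.converged:
        log.warning("unconverged logistic fit for animal %s (%s, %s): no dilation component",
                    animal_id, bed.value, agonist.value)
        return None
    return ComponentValue(
        animal_id=animal_id, bed=bed,
        component=_AGONIST_COMPONENT[agonist],
        value=fit.upper_bound_um, units="μm",
    )


def hypoxic_component(challenge: HypoxicChallenge) -> ComponentValue:
    """Pass the single hypoxic dilation through as a component value.

    The hypoxic stimulus is one PO₂ step, not a concentration series, so no
    fit is involved.  A negative dilation (paradoxical constriction) is kept
    but flagged.
    """
    if challenge.dilation_um < 0:
        log.warning("negative hypoxic dilation %.3g μm for animal %s passed through",
                    challenge.dilation_um, challenge.animal_id)
    return ComponentValue(
        animal_id=challenge.animal_id, bed=challenge.bed,
        component=Component.HYPOXIC_DILATION,
        value=challenge.dilation_um, units="μm",
    )
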