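"""Replica-set and traditional survival analysis.

The replica-set design scores each well of ~25 animals once (alive/dead
counts at a single timepoint) and discards it, so a condition's data are
independent cross-sectional binomial observations rather than a tracked
cohort.  Survival over time is modelled with a two-parameter logit curve

    p(t) = 1 / (1 + exp(a*t - b))

where ``a`` is the logit slope (per time unit; a > 0 means declining
survival) and ``b`` the intercept.  The maximum-likelihood (a, b) for
binomial counts is found by iteratively reweighted least squares — this is
ordinary logistic regression of survival on time, with the well counts as
the binomial denominators.  Derived summaries:

* LD50 = b / a           (time of 50% survival)
* maximum life           (time the fitted curve drops to 5% survival,
                          (b + ln 19) / a in closed form)

Traditional longitudinal assays (one death day per animal, with optional
right-censoring) are summarised with the Kaplan-Meier product-limit
estimator and compared with the Mantel-Cox log-rank test; both are
delegated to :mod:`lifelines`.

The IRLS kernel is vectorised across many datasets at once
(:func:`irls_batch`) so that the bootstrap and permutation machinery in
:mod:`replilife.resampling` can refit thousands of resampled replicates in
a handful of array operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import (
    EmptyInputError,
    InsufficientDataError,
    SeparationError,
    ZeroReferenceError,
    ZeroSlopeError,
)

__all__ = [
    "MortalityObservation",
    "ObservationSet",
    "LogitFit",
    "LifespanEvent",
    "KMCurve",
    "LogRankResult",
    "fit_logit",
    "ld50",
    "max_life",
    "predict_survival",
    "kaplan_meier",
    "logrank_test",
    "percent_change",
    "irls_batch",
]

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MortalityObservation:
    """One well scored once: the atomic unit of the replica-set design.

    Parameters
    ----------
    timepoint : float
        Age at scoring, in the set's time unit (days for lifespan,
        hours for acute stress assays).  Nonnegative.
    n_alive, n_dead : float
        Counts of animals alive/dead in the well.  Fractional values are
        accepted (expected-count limits are useful in tests) but must be
        nonnegative and sum to at least one animal.
    condition : str
        Strain x treatment label.
    trial : str
        Independent-trial label (biological replicate).
    """

    timepoint: float
    n_alive: float
    n_dead: float
    condition: str = ""
    trial: str = ""

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ValueError(f"timepoint must be >= 0, got {self.timepoint}")
        if self.n_alive < 0 or self.n_dead < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_alive + self.n_dead < 1:
            raise ValueError("a retained well must contain at least one animal")


@dataclass
class ObservationSet:
    """All wells for one condition, ready for fitting.

    Wells never mix time units; days and hours are carried as metadata only.
    """

    observations: list[MortalityObservation]
    time_unit: str = "days"
    condition: str = ""

    def __post_init__(self) -> None:
        if self.time_unit not in ("days", "hours"):
            raise ValueError("time_unit must be 'days' or 'hours'")
        if not self.condition and self.observations:
            self.condition = self.observations[0].condition

    def __len__(self) -> int:
        return len(self.observations)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (timepoints, n_alive, n_dead) as float arrays."""
        t = np.array([o.timepoint for o in self.observations], dtype=float)
        alive = np.array([o.n_alive for o in self.observations], dtype=float)
        dead = np.array([o.n_dead for o in self.observations], dtype=float)
        return t, alive, dead

    @classmethod
    def from_arrays(
        cls,
        timepoints: Sequence[float],
        n_alive: Sequence[float],
        n_dead: Sequence[float],
        condition: str = "",
        time_unit: str = "days",
        trial: str = "",
    ) -> "ObservationSet":
        obs = [
            MortalityObservation(float(t), float(a), float(d), condition, trial)
            for t, a, d in zip(timepoints, n_alive, n_dead, strict=True)
        ]
        return cls(obs, time_unit=time_unit, condition=condition)


@dataclass(frozen=True)
class LogitFit:
    """Fitted two-parameter logit survival curve."""

    a: float
    b: float
    n_obs: int
    converged: bool
    loglik: float

    @property
    def ld50(self) -> float:
        return ld50(self)

    @property
    def max_life(self) -> float:
        return max_life(self)


@dataclass(frozen=True)
class LifespanEvent:
    """One animal's death (or censoring) day in a traditional assay."""

    day: float
    censored: bool = False
    condition: str = ""

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError("day must be >= 0")


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit curve evaluated at the death times."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    median: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# Vectorised IRLS kernel
# ---------------------------------------------------------------------------

_ETA_CLIP = 30.0  # |logit| beyond this is numerically saturated


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


def irls_batch(
    t: np.ndarray,
    alive: np.ndarray,
    dead: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit p_survive(t) = 1/(1+exp(a*t-b)) to many datasets at once.

    ``t``, ``alive`` and ``dead`` have shape (R, n): R independent datasets
    of n wells each.  Returns arrays ``(a, b, converged)`` of shape (R,).

    This is Newton/Fisher scoring for binomial logistic regression of the
    alive count on time (linear predictor eta = b - a*t), with the 2x2
    normal equations solved in closed form.  Rows whose information matrix
    degenerates (perfect separation, a single distinct timepoint) stop
    updating and are reported unconverged; callers decide how to treat
    them.  Convergence is max-abs parameter change < ``tol`` within
    ``max_iter`` iterations.
    """
    t = np.atleast_2d(np.asarray(t, dtype=float))
    y = np.atleast_2d(np.asarray(alive, dtype=float))
    n = y + np.atleast_2d(np.asarray(dead, dtype=float))

    # Start from a weighted LS fit of the empirical logits: robust even when
    # the pooled survival never crosses 0.5, and fully vectorised.
    p0 = (y + 0.5) / (n + 1.0)
    z = np.log(p0 / (1.0 - p0))
    w0 = n * p0 * (1.0 - p0)
    b, a = _solve_2x2(t, w0, w0 * z, w0 * z * t)

    converged = np.zeros(t.shape[0], dtype=bool)
    active = np.ones_like(converged)
    for _ in range(max_iter):
        eta = b[:, None] - a[:, None] * t
        p = _expit(eta)
        w = n * p * (1.0 - p)
        resid = y - n * p
        db, da = _solve_2x2(t, w, resid, resid * t)
        # degenerate rows: freeze
        bad = ~np.isfinite(db) | ~np.isfinite(da)
        db = np.where(bad | ~active, 0.0, db)
        da = np.where(bad | ~active, 0.0, da)
        b = b + db
        a = a + da
        newly = active & (np.maximum(np.abs(da), np.abs(db)) < tol) & ~bad
        converged |= newly
        active &= ~newly
        if not active.any():
            break
    return a, b, converged


def _solve_2x2(
    t: np.ndarray, w: np.ndarray, u_terms: np.ndarray, v_terms: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the weighted normal equations for the model z = b - a*t.

    Row-wise: A*b - B*a = u ;  -B*b + C*a = -v, with A = sum(w),
    B = sum(w*t), C = sum(w*t^2), u = sum(u_terms), v = sum(v_terms).
    Returns (b, a); rows with a singular system come back as NaN.
    """
    A = w.sum(axis=1)
    B = (w * t).sum(axis=1)
    C = (w * t * t).sum(axis=1)
    u = u_terms.sum(axis=1)
    v = v_terms.sum(axis=1)
    det = A * C - B * B
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (C * u - B * v) / det
        a = (B * u - A * v) / det
    return b, a


def binomial_loglik(
    a: float | np.ndarray,
    b: float | np.ndarray,
    t: np.ndarray,
    alive: np.ndarray,
    dead: np.ndarray,
) -> float | np.ndarray:
    """Binomial log-likelihood (up to the data-only binomial coefficient)."""
    eta = np.asarray(b) - np.asarray(a) * t
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    # log p = -log(1+e^-eta); log(1-p) = -eta - log(1+e^-eta)
    log1pe = np.log1p(np.exp(-np.abs(eta))) + np.maximum(-eta, 0.0)
    ll = alive * (-log1pe) + dead * (-eta - log1pe)
    return ll.sum(axis=-1)


# ---------------------------------------------------------------------------
# Separation diagnostics
# ---------------------------------------------------------------------------


def detect_separation(
    t: np.ndarray, alive: np.ndarray, dead: np.ndarray
) -> str | None:
    """Classify perfect separation of deaths in time for one dataset.

    Returns ``None`` when the MLE is finite (any mixed well, or pure wells
    whose times interleave), else one of ``"all_alive"``, ``"all_dead"``,
    ``"split"`` (every well pure and all fully-alive wells strictly precede
    all fully-dead wells).
    """
    if np.all(dead == 0):
        return "all_alive"
    if np.all(alive == 0):
        return "all_dead"
    mixed = (alive > 0) & (dead > 0)
    if mixed.any():
        return None
    if t[alive > 0].max() < t[dead > 0].min():
        return "split"
    return None


def separation_midpoint(t: np.ndarray, alive: np.ndarray, dead: np.ndarray, kind: str) -> float:
    """Surrogate LD50 for a perfectly separated dataset.

    The 50% crossing is only known to lie between the last fully-alive and
    first fully-dead timepoint; the midpoint of that interval is returned.
    One-sided degeneracies fall back on the extreme observed timepoint
    (a lower/upper bound on the crossing).
    """
    if kind == "all_alive":
        return float(t.max())
    if kind == "all_dead":
        return float(t.min())
    return float((t[alive > 0].max() + t[dead > 0].min()) / 2.0)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def fit_logit(obs: ObservationSet, tol: float = 1e-8, max_iter: int = 100) -> LogitFit:
    """Maximum-likelihood fit of the two-parameter logit survival curve.

    Raises
    ------
    InsufficientDataError
        Fewer than two distinct timepoints.
    SeparationError
        Deaths perfectly separated in time (all wells fully alive, all
        fully dead, or a clean alive-before-dead time split): the
        likelihood is unbounded and (a, b) run away to infinity.
    """
    t, alive, dead = obs.arrays()
    if len(np.unique(t)) < 2:
        raise InsufficientDataError(
            f"need >= 2 distinct timepoints, got {len(np.unique(t))}"
        )
    kind = detect_separation(t, alive, dead)
    if kind is not None:
        raise SeparationError(
            f"perfect separation ({kind}): logit likelihood is unbounded"
        )
    a, b, conv = irls_batch(t[None, :], alive[None, :], dead[None, :], tol, max_iter)
    ll = float(binomial_loglik(a[0], b[0], t, alive, dead))
    return LogitFit(a=float(a[0]), b=float(b[0]), n_obs=len(obs), converged=bool(conv[0]), loglik=ll)


def ld50(fit: LogitFit) -> float:
    """Time of 50% survival on the fitted curve: b/a."""
    if fit.a == 0:
        raise ZeroSlopeError("LD50 undefined for zero logit slope")
    return fit.b / fit.a


def max_life(fit: LogitFit, threshold: float = 0.05) -> float:
    """Time the fitted curve crosses ``threshold`` survival (default 5%).

    Closed form: t = (b + ln((1-threshold)/threshold)) / a; for the 5%
    rule this is (b + ln 19)/a.  Uses the fitted curve, not observed data.
    """
    if fit.a == 0:
        raise ZeroSlopeError("maximum life undefined for zero logit slope")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return (fit.b + math.log((1.0 - threshold) / threshold)) / fit.a


def predict_survival(fit: LogitFit, t: float | np.ndarray) -> float | np.ndarray:
    """Survival probability 1/(1+exp(a*t-b)) at time(s) ``t``."""
    out = _expit(fit.b - fit.a * np.asarray(t, dtype=float))
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def _events_to_arrays(events: Iterable[LifespanEvent]) -> tuple[np.ndarray, np.ndarray]:
    ev = list(events)
    days = np.array([e.day for e in ev], dtype=float)
    observed = np.array([not e.censored for e in ev], dtype=bool)
    return days, observed


def kaplan_meier(events: Iterable[LifespanEvent]) -> KMCurve:
    """Product-limit survival estimate for a traditional lifespan assay.

    The reported median is the first time survival drops to <= 0.5
    (infinity when the curve never reaches it).
    """
    days, observed = _events_to_arrays(events)
    if days.size == 0 or not observed.any():
        raise EmptyInputError("Kaplan-Meier needs at least one uncensored event")
    # Running product (1 - d_i/n_i) at each death time.  Counts are
    # integers, so the product is rational; accumulating it exactly makes
    # the uncensored curve equal the empirical survivor function
    # bit-for-bit rather than to within float product error.
    times = np.unique(days[observed])
    surv = np.empty_like(times)
    n_risk = np.empty_like(times)
    s = Fraction(1)
    for k, ti in enumerate(times):
        n_i = int(np.sum(days >= ti))
        d_i = int(np.sum((days == ti) & observed))
        s *= Fraction(n_i - d_i, n_i)
        surv[k] = float(s)
        n_risk[k] = n_i
    below = surv <= 0.5
    median = float(times[below][0]) if below.any() else math.inf
    return KMCurve(times=times, survival=surv, n_at_risk=n_risk, median=median)


def logrank_test(
    events_a: Iterable[LifespanEvent], events_b: Iterable[LifespanEvent]
) -> LogRankResult:
    """Mantel-Cox log-rank comparison of two traditional lifespan arms.

    Unweighted, no continuity correction; chi-squared statistic on 1 df.
    """
    da, oa = _events_to_arrays(events_a)
    db, ob = _events_to_arrays(events_b)
    if da.size == 0 or not oa.any() or db.size == 0 or not ob.any():
        raise EmptyInputError("each group needs at least one uncensored event")
    res = _ll_logrank(da, db, event_observed_A=oa, event_observed_B=ob)
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def percent_change(reference: float, comparison: float, decimals: int = 1) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``.

    100*(comparison - reference)/reference, rounded half-away-from-zero to
    ``decimals`` places — the convention used for every reported effect
    size (median lifespan, LD50, bound-peak fractions).
    """
    if reference == 0:
        raise ZeroReferenceError("percent change from a zero reference is undefined")
    raw = 100.0 * (comparison - reference) / reference
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(raw)).quantize(q, rounding=ROUND_HALF_UP))
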