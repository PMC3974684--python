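"""Nonparametric uncertainty and hypothesis tests on the logit LD50.

The resampling unit is the WELL: in the replica-set design each well is an
independent cross-sectional observation, so bootstrap draws wells with
replacement and the permutation test swaps condition labels between wells.
Defaults follow the published protocol (K = 10,000 resamples).

Perfect separation inside a resampled replicate (all drawn wells fully
alive, fully dead, or cleanly split in time) is expected at K = 10,000 and
must not abort a run: such replicates are assigned the midpoint of the
separating time interval as a surrogate LD50, flagged, and kept countable.

All routines take a :class:`ResampleConfig`; given the same seed and
inputs the outputs are bit-identical.  Replicate randomness for the
four-condition ratio test is split from one seed via ``SeedSequence``
spawning so conditions draw from independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival import (
    ObservationSet,
    detect_separation,
    fit_logit,
    irls_batch,
    ld50,
    separation_midpoint,
)

__all__ = [
    "ResampleConfig",
    "LD50Interval",
    "PermutationResult",
    "RatioResult",
    "bootstrap_ld50",
    "permutation_ld50_test",
    "ratio_ld50_test",
]


@dataclass(frozen=True)
class ResampleConfig:
    """Knobs shared by all resampling routines.

    K : number of resamples (published default 10,000)
    seed : RNG seed; None draws fresh entropy
    unit : resampling unit; only "well" is meaningful for replica sets
    """

    K: int = 10_000
    seed: int | None = None
    unit: str = "well"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.unit != "well":
            raise ValueError("only well-level resampling is supported")


@dataclass(frozen=True)
class LD50Interval:
    """Point estimate with 95% percentile-bootstrap bounds."""

    point: float
    lower: float
    upper: float
    K_effective: int
    K: int


@dataclass(frozen=True)
class PermutationResult:
    observed_delta: float
    p_value: float
    K: int
    n_flagged: int = 0


@dataclass(frozen=True)
class RatioResult:
    """Ratio-of-LD50 comparison between two genetic backgrounds.

    ``observed_delta`` is (treat_A/ctrl_A) - (treat_B/ctrl_B); each ratio
    also carries its own 95% bootstrap CI.
    """

    ratio_a: float
    ratio_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    observed_delta: float
    p_value: float
    K: int
    n_flagged: int = 0


# ---------------------------------------------------------------------------
# Batched LD50 with separation fallback
# ---------------------------------------------------------------------------


def _batch_ld50(
    t: np.ndarray, alive: np.ndarray, dead: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row LD50 for a (R, n) batch of resampled datasets.

    Rows with perfect separation or a single distinct timepoint get the
    surrogate midpoint LD50 and a flag; everything else is the IRLS MLE
    b/a.  Returns (ld50s, flagged) of shape (R,).
    """
    R = t.shape[0]
    out = np.empty(R)
    flagged = np.zeros(R, dtype=bool)

    single_tp = (t == t[:, :1]).all(axis=1)
    no_dead = (dead == 0).all(axis=1)
    no_alive = (alive == 0).all(axis=1)
    any_mixed = ((alive > 0) & (dead > 0)).any(axis=1)
    # candidate split rows need the per-row time comparison
    maybe_split = ~single_tp & ~no_dead & ~no_alive & ~any_mixed

    a, b, _ = irls_batch(t, alive, dead)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = b / a

    for i in np.flatnonzero(single_tp):
        out[i] = t[i, 0]
        flagged[i] = True
    for i in np.flatnonzero(~single_tp & (no_dead | no_alive)):
        kind = "all_alive" if no_dead[i] else "all_dead"
        out[i] = separation_midpoint(t[i], alive[i], dead[i], kind)
        flagged[i] = True
    for i in np.flatnonzero(maybe_split):
        kind = detect_separation(t[i], alive[i], dead[i])
        if kind is not None:
            out[i] = separation_midpoint(t[i], alive[i], dead[i], kind)
            flagged[i] = True
    return out, flagged


def _resample_ld50s(
    obs: ObservationSet, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    t, alive, dead = obs.arrays()
    n = t.size
    idx = rng.integers(0, n, size=(K, n))
    return _batch_ld50(t[idx], alive[idx], dead[idx])


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def bootstrap_ld50(obs: ObservationSet, cfg: ResampleConfig) -> LD50Interval:
    """95% percentile-bootstrap confidence interval on the LD50.

    Wells are resampled with replacement (same number of wells), the logit
    curve refit per replicate, and the 2.5/97.5 percentiles of the
    replicate LD50 distribution reported.  Flagged (separated) replicates
    contribute their surrogate LD50; ``K_effective`` counts the replicates
    with a genuine refit.
    """
    point = ld50(fit_logit(obs))
    rng = np.random.default_rng(cfg.seed)
    ld50s, flagged = _resample_ld50s(obs, cfg.K, rng)
    lower, upper = np.percentile(ld50s, [2.5, 97.5])
    return LD50Interval(
        point=point,
        lower=float(lower),
        upper=float(upper),
        K_effective=int(cfg.K - flagged.sum()),
        K=cfg.K,
    )


def permutation_ld50_test(
    obs_a: ObservationSet,
    obs_b: ObservationSet,
    cfg: ResampleConfig,
    stratify_by_trial: bool = False,
) -> PermutationResult:
    """Two-sided label-swap permutation test on the LD50 difference.

    Wells of both conditions are pooled; condition labels are randomly
    reassigned preserving group sizes; both curves are refit and the
    absolute resampled difference compared to the observed difference.
    p = (#{|delta*| >= |delta_obs|} + 1)/(K + 1), so p >= 1/(K+1) always.

    With ``stratify_by_trial`` labels are only swapped between wells of
    the same trial, preserving any per-trial structure.
    """
    fa, fb = fit_logit(obs_a), fit_logit(obs_b)
    delta_obs = ld50(fa) - ld50(fb)

    ta, ya, da = obs_a.arrays()
    tb, yb, db = obs_b.arrays()
    t = np.concatenate([ta, tb])
    alive = np.concatenate([ya, yb])
    dead = np.concatenate([da, db])
    na, n = ta.size, ta.size + tb.size

    rng = np.random.default_rng(cfg.seed)
    if stratify_by_trial:
        trials = np.array(
            [o.trial for o in obs_a.observations] + [o.trial for o in obs_b.observations]
        )
        idx = _stratified_permutations(trials, cfg.K, rng)
    else:
        idx = rng.permuted(np.tile(np.arange(n), (cfg.K, 1)), axis=1)

    ia, ib = idx[:, :na], idx[:, na:]
    ld_a, fl_a = _batch_ld50(t[ia], alive[ia], dead[ia])
    ld_b, fl_b = _batch_ld50(t[ib], alive[ib], dead[ib])
    delta = ld_a - ld_b
    count = int(np.sum(np.abs(delta) >= abs(delta_obs)))
    return PermutationResult(
        observed_delta=delta_obs,
        p_value=(count + 1) / (cfg.K + 1),
        K=cfg.K,
        n_flagged=int(fl_a.sum() + fl_b.sum()),
    )


def _stratified_permutations(
    trials: np.ndarray, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Index matrix (K, n) permuting positions only within each trial."""
    n = trials.size
    idx = np.tile(np.arange(n), (K, 1))
    for tr in np.unique(trials):
        cols = np.flatnonzero(trials == tr)
        idx[:, cols] = rng.permuted(idx[:, cols], axis=1)
    return idx


def ratio_ld50_test(
    ctrl_a: ObservationSet,
    treat_a: ObservationSet,
    ctrl_b: ObservationSet,
    treat_b: ObservationSet,
    cfg: ResampleConfig,
) -> RatioResult:
    """Compare the treatment/control LD50 ratio between two backgrounds.

    The statistic is (LD50_treat_A/LD50_ctrl_A) - (LD50_treat_B/LD50_ctrl_B).
    Each of the four conditions' wells is bootstrapped with replacement
    (K replicates each, independent streams split from one seed), giving a
    replicate distribution of the ratio difference.  The two-sided p-value
    counts replicates at least as far from the observed statistic as zero
    is: p = (#{|delta* - delta_obs| >= |delta_obs|} + 1)/(K + 1) — the
    bootstrap test of whether zero is inside the difference distribution.
    """
    fits = [fit_logit(o) for o in (ctrl_a, treat_a, ctrl_b, treat_b)]
    l_ca, l_ta, l_cb, l_tb = (ld50(f) for f in fits)
    ratio_a, ratio_b = l_ta / l_ca, l_tb / l_cb
    delta_obs = ratio_a - ratio_b

    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    boots = []
    n_flagged = 0
    for o, ss in zip((ctrl_a, treat_a, ctrl_b, treat_b), streams):
        vals, fl = _resample_ld50s(o, cfg.K, np.random.default_rng(ss))
        boots.append(vals)
        n_flagged += int(fl.sum())
    b_ca, b_ta, b_cb, b_tb = boots
    with np.errstate(divide="ignore", invalid="ignore"):
        r_a = b_ta / b_ca
        r_b = b_tb / b_cb
    delta = r_a - r_b
    count = int(np.sum(np.abs(delta - delta_obs) >= abs(delta_obs)))
    ci_a = tuple(float(x) for x in np.percentile(r_a, [2.5, 97.5]))
    ci_b = tuple(float(x) for x in np.percentile(r_b, [2.5, 97.5]))
    return RatioResult(
        ratio_a=ratio_a,
        ratio_b=ratio_b,
        ci_a=ci_a,
        ci_b=ci_b,
        observed_delta=delta_obs,
        p_value=(count + 1) / (cfg.K + 1),
        K=cfg.K,
        n_flagged=n_flagged,
    )
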