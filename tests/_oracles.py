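"""Independent reference implementations used as test oracles.

Everything here deliberately avoids the package's own code paths:
log-likelihoods are re-derived from the binomial pmf, the product-limit
estimator is the textbook running product, and the log-rank statistic is
built from per-event-time hypergeometric moments by explicit enumeration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize


def binom_loglik(a: float, b: float, t, alive, dead) -> float:
    """Binomial log-likelihood of the logit survival curve, from scratch."""
    t = np.asarray(t, float)
    alive = np.asarray(alive, float)
    dead = np.asarray(dead, float)
    eta = np.clip(b - a * t, -500, 500)
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return float(np.sum(alive * np.log(p) + dead * np.log(1.0 - p)))


def grid_refine_mle(t, alive, dead, a0: float, b0: float, half_width: float = 0.5):
    """Dense 200x200 grid around (a0, b0) followed by local refinement.

    Returns (a, b, loglik) of the best point found — a brute-force MLE.
    """
    a_grid = np.linspace(a0 * (1 - half_width), a0 * (1 + half_width), 200)
    b_grid = np.linspace(b0 * (1 - half_width), b0 * (1 + half_width), 200)
    best = (-math.inf, a0, b0)
    for a in a_grid:
        for b in b_grid:
            ll = binom_loglik(a, b, t, alive, dead)
            if ll > best[0]:
                best = (ll, a, b)
    res = minimize(
        lambda ab: -binom_loglik(ab[0], ab[1], t, alive, dead),
        x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20_000},
    )
    return float(res.x[0]), float(res.x[1]), float(-res.fun)


def grid_best_loglik(t, alive, dead, a0: float, b0: float, half_width: float = 0.5):
    """Best log-likelihood over the raw 200x200 grid (no refinement)."""
    a_grid = np.linspace(a0 * (1 - half_width), a0 * (1 + half_width), 200)
    b_grid = np.linspace(b0 * (1 - half_width), b0 * (1 + half_width), 200)
    ll = np.array([[binom_loglik(a, b, t, alive, dead) for b in b_grid] for a in a_grid])
    return float(ll.max())


def km_product_limit(days, observed):
    """Textbook product-limit estimate: times, survival, at-risk counts."""
    days = np.asarray(days, float)
    observed = np.asarray(observed, bool)
    times = np.unique(days[observed])
    surv, at_risk = [], []
    s = 1.0
    for ti in times:
        n_i = np.sum(days >= ti)
        d_i = np.sum((days == ti) & observed)
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
    return times, np.array(surv), np.array(at_risk, float)


def logrank_by_enumeration(days_a, obs_a, days_b, obs_b):
    """Mantel-Cox chi-squared from per-event-time hypergeometric moments."""
    days_a, days_b = np.asarray(days_a, float), np.asarray(days_b, float)
    obs_a, obs_b = np.asarray(obs_a, bool), np.asarray(obs_b, bool)
    all_days = np.concatenate([days_a, days_b])
    all_obs = np.concatenate([obs_a, obs_b])
    event_times = np.unique(all_days[all_obs])
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        n1 = np.sum(days_a >= ti)
        n2 = np.sum(days_b >= ti)
        n = n1 + n2
        d = np.sum((all_days == ti) & all_obs)
        d1 = np.sum((days_a == ti) & obs_a)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    from scipy.stats import chi2 as chi2_dist

    return float(chi2), float(chi2_dist.sf(chi2, 1))


def chi2_hand(k_in, n_in, k_out, n_out):
    """Pearson chi-squared of a 2x2 table by direct O/E expansion."""
    obs = np.array([[k_in, n_in - k_in], [k_out, n_out - k_out]], float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def assign_targets_bruteforce(peaks, genes, window=(-700, 100)):
    """All-pairs double loop over (peak, gene); the assignment oracle."""
    lo, hi = window
    out: dict[str, set[str]] = {}
    for p in peaks:
        mid = (p.start + p.end - 1) // 2
        for g in genes:
            if g.chrom != p.chrom:
                continue
            off = mid - g.tss if g.strand == "+" else g.tss - mid
            if lo <= off <= hi:
                out.setdefault(p.factor, set()).add(g.id)
    return out
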