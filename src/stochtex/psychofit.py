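"""Psychometric-function fitting: three-parameter modified Weibull.

Percent correct in the two-response oddest-man-out task rises from the 50%
chance floor toward an asymptote 1 - lambda:

    P(x) = 0.5 + (0.5 - lambda) * (1 - exp(-(x / alpha)^beta))

with scale alpha (> 0, in units of the manipulated parameter), slope beta
(> 0) and lapse rate lambda in [0, 0.5).  Parameters are estimated by
unweighted least squares on the observed proportions; the just-noticeable
difference (JND) is the level giving a criterion proportion correct,
conventionally 71% (the convergence point of a 2-up 1-down staircase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "PsychometricData",
    "PsychometricFit",
    "weibull3",
    "fit_psychometric",
    "jnd_at",
    "confidence_intervals",
]


@dataclass
class PsychometricData:
    """Per-level correct/total counts."""

    levels: np.ndarray
    n_correct: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        if not (self.levels.shape == self.n_correct.shape == self.n_trials.shape):
            raise ValueError("levels, n_correct, n_trials must have equal shapes")
        if np.any(self.n_correct > self.n_trials) or np.any(self.n_correct < 0):
            raise ValueError("need 0 <= n_correct <= n_trials")
        if np.unique(self.levels).size < 4:
            raise ValueError("need at least 4 distinct levels for a 3-parameter fit")

    @property
    def proportions(self) -> np.ndarray:
        return self.n_correct / self.n_trials


@dataclass
class PsychometricFit:
    alpha: float
    beta: float
    lam: float
    jnd71: float
    rss: float
    converged: bool = True
    jnd_in_range: bool = True


def weibull3(x, alpha: float, beta: float, lam: float):
    """P(x) = 0.5 + (0.5 - lam)(1 - exp(-(x/alpha)^beta)); P(0) = 0.5."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if not 0.0 <= lam < 0.5:
        raise ValueError("lapse rate must lie in [0, 0.5)")
    x = np.asarray(x, dtype=float)
    return 0.5 + (0.5 - lam) * (1.0 - np.exp(-np.power(np.maximum(x, 0.0) / alpha, beta)))


def jnd_at(fit: PsychometricFit, criterion: float = 0.71) -> float:
    """Closed-form inverse of the fitted curve at ``criterion`` correct."""
    if not 0.5 < criterion < 1.0 - fit.lam:
        raise ValueError(
            f"criterion {criterion} outside (0.5, {1.0 - fit.lam:.3f}) for this fit"
        )
    frac = (criterion - 0.5) / (0.5 - fit.lam)
    return float(fit.alpha * (-np.log(1.0 - frac)) ** (1.0 / fit.beta))


def _rss(params, x, p_obs) -> float:
    alpha, beta, lam = params
    with np.errstate(over="ignore"):
        pred = 0.5 + (0.5 - lam) * (1.0 - np.exp(-np.power(x / alpha, beta)))
    return float(np.sum((p_obs - pred) ** 2))


def fit_psychometric(
    data: PsychometricData,
    criterion: float = 0.71,
    lapse_max: float = 0.25,
) -> PsychometricFit:
    """Least-squares Weibull fit with a multi-start over a log-spaced alpha grid.

    The lapse rate is bounded above by ``lapse_max`` (free lapse rates are
    notorious for collapsing the asymptote into the data ceiling on noisy
    proportions; 0.25 still allows severe lapsing while keeping the 71%
    point defined).  Flags (rather than raises) two degenerate outcomes:
    non-convergence, and a criterion level outside the tested range
    (extrapolated JND).
    """
    if not 0.0 <= lapse_max < 0.5:
        raise ValueError("lapse_max must lie in [0, 0.5)")
    x = data.levels
    p_obs = data.proportions
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("need at least one positive level")
    alpha_grid = np.geomspace(pos.min() / 4.0, pos.max() * 4.0, 9)
    beta_grid = (0.7, 1.5, 3.0)
    best = None
    bounds = [(1e-9, None), (1e-3, 50.0), (0.0, lapse_max)]
    for a0 in alpha_grid:
        for b0 in beta_grid:
            res = optimize.minimize(
                _rss,
                x0=[a0, b0, 0.01],
                args=(x, p_obs),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-14, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
    alpha, beta, lam = best.x
    converged = bool(best.success)
    fit = PsychometricFit(
        alpha=float(alpha), beta=float(beta), lam=float(lam),
        jnd71=np.nan, rss=float(best.fun), converged=converged,
    )
    asymptote = 1.0 - lam
    if criterion >= asymptote - 1e-9:
        fit.jnd_in_range = False
        warnings.warn("criterion lies at or above the fitted asymptote; JND undefined")
        return fit
    jnd = jnd_at(fit, criterion)
    fit.jnd71 = jnd
    if not (pos.min() <= jnd <= pos.max()):
        fit.jnd_in_range = False
        warnings.warn(
            f"JND {jnd:.3g} lies outside the tested level range "
            f"[{pos.min():.3g}, {pos.max():.3g}] (extrapolated)"
        )
    return fit


def confidence_intervals(
    data: PsychometricData,
    fit: PsychometricFit,
    n_boot: int = 500,
    criterion: float = 0.71,
    rng: np.random.Generator | None = None,
    ci: float = 0.95,
) -> dict:
    """Percentile bootstrap CI for the JND, resampling binomial counts per level.

    Replicates whose fit fails or whose JND is undefined are dropped and
    counted in the returned ``n_failed``.
    """
    if n_boot < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    rng = rng or np.random.default_rng()
    p_hat = data.proportions
    bounds = [(1e-9, None), (1e-3, 50.0), (0.0, max(fit.lam, 0.25))]
    x0 = [fit.alpha, fit.beta, fit.lam]
    jnds = []
    n_failed = 0
    for _ in range(n_boot):
        k = rng.binomial(data.n_trials, p_hat)
        # warm-start each replicate from the point fit (the resampled
        # surface is a small perturbation of the original one)
        res = optimize.minimize(
            _rss, x0=x0, args=(data.levels, k / data.n_trials),
            method="L-BFGS-B", bounds=bounds,
        )
        alpha, beta, lam = res.x
        if not res.success or criterion >= 1.0 - lam - 1e-9:
            n_failed += 1
            continue
        bfit = PsychometricFit(float(alpha), float(beta), float(lam), np.nan, float(res.fun))
        jnd = jnd_at(bfit, criterion)
        if np.isfinite(jnd):
            jnds.append(jnd)
        else:
            n_failed += 1
    if not jnds:
        raise RuntimeError("all bootstrap replicates failed")
    lo, hi = np.percentile(jnds, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    return {"jnd": (float(lo), float(hi)), "n_failed": n_failed, "n_used": len(jnds)}
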