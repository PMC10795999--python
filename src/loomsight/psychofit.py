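"""Psychometric fitting and exact sign-flip permutation inference.

Hit/miss discrimination of looming trajectories is summarised by a
cumulative-normal psychometric model: the probability of a "hit"
response at extrapolated impact offset ``x`` (cm from the nasion) is

    P(hit | x) = 1 − Φ((x − μ) / σ)

so responses fall from near-certain "hit" at the face midline to
near-certain "miss" at large offsets.  ``μ`` locates the 50% point at
the edge of the head and ``σ`` is the discrimination threshold; the
sensitivity statistic is ``ln(1/σ)`` (larger is better — note some
reports typeset this as "ln(1σ)", which is read as ln(1/σ) here).
Paired sensitivities (e.g. upper vs lower visual field) are compared
with an exact sign-flip permutation test that enumerates all 2^n sign
assignments when feasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PsychometricFit",
    "PermutationTestResult",
    "fit_psychometric",
    "discrimination_sensitivity",
    "exact_sign_permutation",
]


@dataclass
class PsychometricFit:
    """Maximum-likelihood cumulative-normal fit of hit-rate data."""

    mu: float  # cm, impact offset at 50% hit response
    sigma: float  # cm, SD of the normal CDF
    log_likelihood: float
    n_trials: np.ndarray  # per level
    impact_points: np.ndarray
    converged: bool = True
    identifiable: bool = True

    @property
    def sensitivity(self) -> float:
        """ln(1/σ); the discrimination-sensitivity statistic."""
        return discrimination_sensitivity(self)

    def predict(self, x) -> np.ndarray:
        return 1.0 - stats.norm.cdf((np.asarray(x, float) - self.mu) / self.sigma)


@dataclass
class PermutationTestResult:
    observed_stat: float
    p_value: float
    n_permutations: int
    exact: bool
    seed: int | None = None
    null_distribution: np.ndarray | None = None


_LOG_SIGMA_BOUNDS = (-7.0, 7.0)


def _nll(params: np.ndarray, x: np.ndarray, n_hit: np.ndarray, n_tot: np.ndarray) -> float:
    mu, log_sigma = params
    sigma = math.exp(log_sigma)
    p = stats.norm.sf((x - mu) / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(n_hit * np.log(p) + (n_tot - n_hit) * np.log(1.0 - p)))


def fit_psychometric(impact_points, n_hit, n_total) -> PsychometricFit:
    """Binomial maximum-likelihood fit of the cumulative-normal model.

    Optimises (μ, log σ) with bounded quasi-Newton from a moment-based
    start plus a small multistart grid.  All-hit or all-miss data are
    non-identifiable: the fit is returned at the box bound with
    ``identifiable=False``.
    """
    x = np.asarray(impact_points, dtype=float)
    h = np.asarray(n_hit, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct impact points")
    if np.any(h < 0) or np.any(n < h) or np.any(n <= 0):
        raise ValueError("counts must satisfy 0 <= n_hit <= n_total, n_total > 0")
    # merge duplicate levels so the likelihood is invariant to data layout
    order = np.argsort(x)
    x, h, n = x[order], h[order], n[order]
    ux, inv = np.unique(x, return_inverse=True)
    uh = np.bincount(inv, weights=h)
    un = np.bincount(inv, weights=n)

    rates = uh / un
    identifiable = bool(rates.min() < 1.0 and rates.max() > 0.0)

    # moment start: probit-transform rates, linear fit of z on x
    z = stats.norm.ppf(np.clip(rates, 0.02, 0.98))
    slope, intercept = np.polyfit(ux, z, 1) if len(ux) > 1 else (-1.0, 0.0)
    if slope >= -1e-6:  # orientation fixed: hit probability decreases with x
        slope = -1.0 / max(np.ptp(ux), 1.0)
    sigma0 = -1.0 / slope
    mu0 = intercept * sigma0

    span = max(np.ptp(ux), 1e-3)
    starts = [(mu0, math.log(max(sigma0, 1e-3)))]
    for m in (ux.mean(), mu0):
        for s in (span / 4, span, span / 10):
            starts.append((m, math.log(s)))
    best = None
    bounds = [(ux.min() - 5 * span, ux.max() + 5 * span), _LOG_SIGMA_BOUNDS]
    for start in starts:
        res = optimize.minimize(
            _nll,
            np.asarray(start),
            args=(ux, uh, un),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    mu, log_sigma = best.x
    return PsychometricFit(
        mu=float(mu),
        sigma=float(math.exp(log_sigma)),
        log_likelihood=-float(best.fun),
        n_trials=un,
        impact_points=ux,
        converged=bool(best.success),
        identifiable=identifiable,
    )


def discrimination_sensitivity(fit) -> float:
    """ln(1/σ) of a psychometric fit (or of a raw σ value)."""
    sigma = fit.sigma if hasattr(fit, "sigma") else float(fit)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return -math.log(sigma)


def exact_sign_permutation(
    paired_differences,
    two_sided: bool = True,
    max_exact_n: int = 20,
    n_montecarlo: int = 10_000,
    seed: int | None = None,
    return_null: bool = False,
) -> PermutationTestResult:
    """Sign-flip permutation test of zero mean for paired differences.

    The statistic is the mean difference.  For n ≤ ``max_exact_n`` all
    2^n sign assignments are enumerated (an exact test); otherwise a
    seeded Monte Carlo null of ``n_montecarlo`` draws is used with the
    identity permutation included.  Two-sided p is the proportion of
    |null| ≥ |observed|.
    """
    d = np.asarray(paired_differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    observed = float(d.mean())
    exact = n <= max_exact_n
    if exact:
        # all sign patterns via the binary expansion of 0..2^n-1 (chunked)
        total = 2**n
        bits = np.arange(n, dtype=np.uint64)
        chunks = []
        for lo in range(0, total, 1 << 16):
            codes = np.arange(lo, min(lo + (1 << 16), total), dtype=np.uint64)
            signs = 1.0 - 2.0 * ((codes[:, None] >> bits) & 1)
            chunks.append(signs @ d / n)
        null = np.concatenate(chunks)
        n_perm = total
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_montecarlo, n))
        signs[0] = 1.0  # include the identity so p > 0
        null = signs @ d / n
        n_perm = n_montecarlo
    if two_sided:
        p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
    else:
        p = float(np.mean(null >= observed - 1e-12))
    return PermutationTestResult(
        observed_stat=observed,
        p_value=p,
        n_permutations=n_perm,
        exact=exact,
        seed=None if exact else seed,
        null_distribution=null if return_null else None,
    )
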