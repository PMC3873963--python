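"""Empirical Bayes estimation of abundance and realized density.

For every Poisson point-process SECR model the number n0 of undetected
individuals has a Poisson full conditional with mean mu(theta) pi0(theta).
The empirical Bayes estimator of abundance is N_hat = n + mu_hat pi0_hat;
its variance combines the conditional-Poisson variance with a delta-method
term propagating the sampling uncertainty of theta_hat.  The same
conditional reasoning yields abundance in subregions of B and per-pixel
maps of realized density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import softmax
from scipy.stats import norm

from .fitting import FitResult
from .statespace import Region, intensity

__all__ = [
    "AbundanceEstimate",
    "n0_conditional_mean",
    "eb_abundance",
    "abundance_in_region",
    "density_map",
    "density_vs_covariate",
]

_GRAD_STEP = 1e-4  # central-difference step on the estimation scale


@dataclass
class AbundanceEstimate:
    """Empirical Bayes abundance estimate with lognormal interval."""

    n: float
    n0_mean: float
    N_hat: float
    var_N: float
    ci_low: float
    ci_high: float
    region_mask: np.ndarray | None = None

    def __repr__(self) -> str:  # compact scientific summary
        return (
            f"AbundanceEstimate(N_hat={self.N_hat:.1f}, "
            f"se={np.sqrt(self.var_N):.1f}, "
            f"ci=({self.ci_low:.1f}, {self.ci_high:.1f}))"
        )


def n0_conditional_mean(context, theta: np.ndarray) -> float:
    """Mean mu(theta) pi0(theta) of the Poisson full conditional of n0.

    Model-agnostic: any context exposing ``mu_pi0`` (trapping-array or
    area-search) works.
    """
    mu, pi0 = context.mu_pi0(np.asarray(theta, dtype=float))
    return mu * pi0


def _gradient(f, theta: np.ndarray, step: float = _GRAD_STEP) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    g = np.zeros(theta.size)
    h = step * np.maximum(1.0, np.abs(theta))
    for i in range(theta.size):
        if not np.isfinite(theta[i]):
            continue  # parameter pinned at a boundary (e.g. p0 = 0)
        e = np.zeros(theta.size)
        e[i] = h[i]
        g[i] = (f(theta + e) - f(theta - e)) / (2.0 * h[i])
    return g


def _lognormal_interval(
    N_hat: float, var_N: float, n_offset: float = 0.0, level: float = 0.95
) -> tuple[float, float]:
    """Moment-matched lognormal interval for a positive estimate.

    When ``n_offset`` > 0 the lognormal is applied to N_hat - n_offset
    (the undetected part) and the offset added back.
    """
    z = norm.ppf(0.5 + level / 2)
    m = N_hat - n_offset
    if m <= 0 or var_N <= 0:
        return (N_hat, N_hat)
    C = np.exp(z * np.sqrt(np.log1p(var_N / m**2)))
    return (n_offset + m / C, n_offset + m * C)


def eb_abundance(
    fit: FitResult,
    level: float = 0.95,
    interval_on: str = "N",
) -> AbundanceEstimate:
    """Empirical Bayes estimate of abundance over the whole state space.

    N_hat = n + mu_hat pi0_hat; var = mu_hat pi0_hat + G' Sigma G with G
    the numeric gradient of mu(theta) pi0(theta) at the MLE (estimation
    scale).  The interval is lognormal, moment-matched on N_hat by
    default; ``interval_on='n0'`` matches on the undetected part instead.
    """
    ctx = fit.context
    n = ctx.n
    theta = fit.theta
    n0_mean = n0_conditional_mean(ctx, theta)
    var = n0_mean
    if fit.vcov is None:
        warnings.warn("no variance-covariance matrix; interval reflects Poisson variation only")
    else:
        g = _gradient(lambda t: n0_conditional_mean(ctx, t), theta)
        var = n0_mean + float(g @ fit.vcov @ g)
    N_hat = n + n0_mean
    offset = float(n) if interval_on == "n0" else 0.0
    lo, hi = _lognormal_interval(N_hat, var, n_offset=offset, level=level)
    return AbundanceEstimate(
        n=n, n0_mean=n0_mean, N_hat=N_hat, var_N=var, ci_low=lo, ci_high=hi
    )


def _center_posterior_weights(fit: FitResult) -> np.ndarray:
    """(n, G) posterior pixel masses of each detected individual's center.

    Bayes rule at theta_hat: weights proportional to
    exp(conditional history loglik) * lam_g * a.
    """
    ctx = fit.context
    ip, _ = ctx.unpack(fit.theta)
    lam = intensity(ctx.ss, ip)
    M = ctx.cond_loglik(fit.theta) + np.log(lam * ctx.ss.pixel_area)[None, :]
    return softmax(M, axis=1)


def abundance_in_region(
    fit: FitResult,
    sub: Region | np.ndarray,
    level: float = 0.95,
    interval_on: str = "N",
) -> AbundanceEstimate:
    """Abundance of activity centers inside a subset of B.

    Sums each detected individual's posterior probability of having its
    center in the subregion, plus the thinned intensity of undetected
    individuals integrated over the subregion.  With sub = B this reduces
    to :func:`eb_abundance`.
    """
    ctx = fit.context
    ss = ctx.ss
    mask = sub if isinstance(sub, np.ndarray) else ss.mask_for(sub)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ss.G,):
        raise ValueError("mask must have one entry per pixel")

    W = _center_posterior_weights(fit)
    pr_in = W[:, mask].sum(axis=1) if ctx.n else np.zeros(0)

    def undetected_mean(theta: np.ndarray) -> float:
        ip, _ = ctx.unpack(theta)
        lam = intensity(ss, ip)
        q = ctx.pixel_nondet_prob(theta)
        return float((lam[mask] * q[mask]).sum() * ss.pixel_area)

    n0_part = undetected_mean(fit.theta)
    det_part = float(pr_in.sum())
    N_hat = det_part + n0_part
    # Poisson floor + detected-membership (Bernoulli) variance + parameter term
    var = n0_part + float((pr_in * (1.0 - pr_in)).sum())
    if fit.vcov is not None:
        g = _gradient(undetected_mean, fit.theta)
        var += float(g @ fit.vcov @ g)
    offset = det_part if interval_on == "n0" else 0.0
    lo, hi = _lognormal_interval(N_hat, var, n_offset=offset, level=level)
    return AbundanceEstimate(
        n=det_part,
        n0_mean=n0_part,
        N_hat=N_hat,
        var_N=var,
        ci_low=lo,
        ci_high=hi,
        region_mask=mask,
    )


def density_map(fit: FitResult) -> np.ndarray:
    """Per-pixel expected realized density of activity centers given the data.

    Detected individuals contribute their center posteriors; undetected
    ones the thinned intensity lam_g * pi0_g.  Summing the map times the
    pixel area over B recovers N_hat.
    """
    ctx = fit.context
    ss = ctx.ss
    ip, _ = ctx.unpack(fit.theta)
    lam = intensity(ss, ip)
    q = ctx.pixel_nondet_prob(fit.theta)
    mass = lam * q * ss.pixel_area
    if ctx.n:
        mass = mass + _center_posterior_weights(fit).sum(axis=0)
    return mass / ss.pixel_area


def density_vs_covariate(
    fit: FitResult,
    values: np.ndarray | None = None,
    level: float = 0.95,
    num: int = 101,
) -> pd.DataFrame:
    """Expected density as a function of the habitat covariate, with a Wald band.

    Returns a DataFrame with columns ``covariate`` (raw scale),
    ``density`` = exp(x(v)' beta_hat) and the ``lo``/``hi`` band computed
    on the log scale.  Requires a fitted habitat (non-intercept-only) model.
    """
    ctx = fit.context
    ss = ctx.ss
    if ss.degree < 1 or ss.X.shape[1] < 2:
        raise ValueError("density_vs_covariate requires a habitat covariate model")
    if values is None:
        raw = ss.cov_mean + ss.cov_sd * ss.X[:, 1]
        values = np.linspace(raw.min(), raw.max(), num)
    values = np.asarray(values, dtype=float)
    Xv = ss.design_row(values)
    beta = fit.theta[: ctx.n_beta]
    eta = Xv @ beta
    if fit.vcov is None:
        se = np.zeros_like(eta)
    else:
        Sb = fit.vcov[: ctx.n_beta, : ctx.n_beta]
        se = np.sqrt(np.maximum((Xv @ Sb * Xv).sum(axis=1), 0.0))
    z = norm.ppf(0.5 + level / 2)
    return pd.DataFrame(
        {
            "covariate": values,
            "density": np.exp(eta),
            "lo": np.exp(eta - z * se),
            "hi": np.exp(eta + z * se),
        }
    )
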