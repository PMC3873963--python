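"""Bayesian fitting by Metropolis-within-Gibbs with n0 retained as a parameter.

The target is the complete-data posterior proportional to
exp(-mu) (mu pi0)^{n0} / n0! * prod_i [marginal history density of
individual i] * [theta].  Because the full conditional of the number of
undetected individuals n0 is exactly Poisson(mu(theta) pi0(theta)), the
sampler alternates an exact Poisson draw of n0 with random-walk
Metropolis updates of each component of theta (natural scale), adapted
toward ~0.3 acceptance during burn-in and frozen afterwards.
Posterior inference about abundance N = n + n0 follows directly from the
retained n0 draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .statespace import Region, intensity

__all__ = [
    "Priors",
    "PosteriorChains",
    "PosteriorSummary",
    "run_mcmc",
    "posterior_N",
    "posterior_N_region",
    "mcse_obm",
]


@dataclass
class Priors:
    """Noninformative priors: normal(0, sd_beta) on beta (or improper flat),
    uniform(0,1) on the detection probability, uniform(0, sigma_max) on sigma."""

    beta_sd: float | None = 10.0
    sigma_max: float | None = None  # default: state-space diagonal

    def log_beta(self, beta: np.ndarray) -> float:
        if self.beta_sd is None:
            return 0.0
        return float(-0.5 * (beta**2).sum() / self.beta_sd**2)


@dataclass
class PosteriorChains:
    """MCMC draws of (theta, n0) plus per-draw mu*pi0 for Rao-Blackwellization."""

    names: list[str]
    theta: np.ndarray  # (M, d) natural scale
    n0: np.ndarray  # (M,) nonnegative integers
    mu_pi0: np.ndarray  # (M,)
    seed: int
    burn_in: int
    accept_rate: dict[str, float] = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.theta.shape[0]

    def post(self, col: str | None = None) -> np.ndarray:
        """Post-burn-in draws of one parameter (or of n0 / mu_pi0)."""
        if col == "n0":
            return self.n0[self.burn_in :]
        if col == "mu_pi0":
            return self.mu_pi0[self.burn_in :]
        j = self.names.index(col)
        return self.theta[self.burn_in :, j]

    def summary(self) -> "np.ndarray":
        import pandas as pd

        rows = []
        for nm in self.names + ["n0"]:
            x = self.post(nm)
            rows.append(
                {
                    "parameter": nm,
                    "mean": x.mean(),
                    "q2.5": np.quantile(x, 0.025),
                    "q97.5": np.quantile(x, 0.975),
                    "mcse_mean": mcse_obm(x),
                }
            )
        return pd.DataFrame(rows)


def _complete_logpost(context, priors: Priors, theta_nat: np.ndarray, n0: int):
    """Log complete-data posterior (up to a constant) and the pieces reused
    by the n0 update.  Returns (logpost, mu, pi0) or (-inf, None, None)
    outside the prior support."""
    d = theta_nat.size
    nb = context.n_beta
    p_det, sigma = theta_nat[nb], theta_nat[nb + 1]
    if not (0.0 < p_det < 1.0) or sigma <= 0:
        return -np.inf, None, None
    if priors.sigma_max is not None and sigma > priors.sigma_max:
        return -np.inf, None, None
    theta_est = context.pack(*context.unpack_natural(theta_nat))
    mu, pi0 = context.mu_pi0(theta_est)
    mupi0 = max(mu * pi0, 1e-300)
    # complete-data posterior = observed-data loglik with the marginal
    # exp(mu pi0) factor swapped for the Poisson(n0; mu pi0) terms
    lp = (
        context.loglik(theta_est)
        - mupi0
        + n0 * np.log(mupi0)
        - gammaln(n0 + 1)
    )
    lp += priors.log_beta(theta_nat[:nb])
    return float(lp), mu, pi0


def _natural_helpers(context):
    """Attach natural-scale pack/unpack helpers to a model context."""
    from scipy.special import expit, logit

    nb = context.n_beta

    def to_natural(theta_est):
        t = np.asarray(theta_est, dtype=float)
        return np.concatenate([t[:nb], [expit(t[nb]), np.exp(t[nb + 1])]])

    def unpack_natural(theta_nat):
        t = np.asarray(theta_nat, dtype=float)
        est = np.concatenate([t[:nb], [logit(t[nb]), np.log(t[nb + 1])]])
        return context.unpack(est)

    context.to_natural = to_natural
    context.unpack_natural = unpack_natural
    return context


def run_mcmc(
    context,
    priors: Priors | None = None,
    M: int = 10_000,
    seed: int = 0,
    init: np.ndarray | None = None,
    burn_in: int | None = None,
    prop_scale: np.ndarray | float | None = None,
    adapt: bool | None = None,
) -> PosteriorChains:
    """Metropolis-within-Gibbs sampler for (theta, n0).

    ``init`` is an estimation-scale parameter vector (e.g. ``fit.theta``
    from the MLE, the recommended initialization); ``prop_scale`` gives
    per-parameter random-walk standard deviations on the natural scale
    (scalar broadcast; 0 freezes a parameter).  When ``prop_scale`` is
    omitted, scales start at modest defaults and adapt during burn-in
    toward ~0.3 acceptance.  Chains are exactly reproducible given seed.
    """
    context = _natural_helpers(context)
    priors = priors or Priors()
    if priors.sigma_max is None:
        r = context.ss.region
        priors = Priors(priors.beta_sd, float(np.hypot(r.width, r.height)))
    if burn_in is None:
        burn_in = M // 10
    if M <= burn_in:
        raise ValueError("M must exceed burn_in")
    rng = np.random.default_rng(seed)
    d = context.n_beta + 2
    names = list(context.names)

    if init is not None:
        theta = context.to_natural(np.asarray(init, dtype=float))
    else:
        theta = context.to_natural(context.default_start())

    if prop_scale is None:
        scales = np.concatenate(
            [np.full(context.n_beta, 0.05), [0.02, 0.05 * theta[-1] + 1e-6]]
        )
        if adapt is None:
            adapt = True
    else:
        scales = np.broadcast_to(np.asarray(prop_scale, dtype=float), (d,)).copy()
        if adapt is None:
            adapt = False

    lp, mu, pi0 = _complete_logpost(context, priors, theta, 0)
    if not np.isfinite(lp):
        raise ValueError("initial parameter values have zero posterior density")
    n0 = int(rng.poisson(mu * pi0))
    lp, mu, pi0 = _complete_logpost(context, priors, theta, n0)

    theta_out = np.empty((M, d))
    n0_out = np.empty(M, dtype=int)
    mupi0_out = np.empty(M)
    acc = np.zeros(d)
    tries = np.zeros(d)
    acc_win = np.zeros(d)
    tries_win = np.zeros(d)
    sigma_hits = 0

    for m in range(M):
        for j in range(d):
            if scales[j] == 0.0:
                continue
            prop = theta.copy()
            prop[j] += rng.normal(0.0, scales[j])
            lp_prop, mu_p, pi0_p = _complete_logpost(context, priors, prop, n0)
            tries[j] += 1
            tries_win[j] += 1
            if np.log(rng.uniform()) < lp_prop - lp:
                theta, lp, mu, pi0 = prop, lp_prop, mu_p, pi0_p
                acc[j] += 1
                acc_win[j] += 1
        if priors.sigma_max is not None and theta[-1] > 0.95 * priors.sigma_max:
            sigma_hits += 1
        # exact Gibbs draw from the Poisson full conditional of n0; the
        # individual-history part of lp is unchanged, so update in place
        mupi0 = max(mu * pi0, 1e-300)
        n0_new = int(rng.poisson(mupi0))
        lp += (
            (n0_new - n0) * np.log(mupi0)
            - gammaln(n0_new + 1)
            + gammaln(n0 + 1)
        )
        n0 = n0_new

        if adapt and m < burn_in and (m + 1) % 50 == 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                rate = np.where(tries_win > 0, acc_win / tries_win, 0.3)
            scales *= np.exp(np.clip(2.0 * (rate - 0.3), -0.7, 0.7))
            acc_win[:] = 0
            tries_win[:] = 0

        theta_out[m] = theta
        n0_out[m] = n0
        mupi0_out[m] = mu * pi0

    with np.errstate(divide="ignore", invalid="ignore"):
        rates = {nm: float(a / t) if t else 1.0 for nm, a, t in zip(names, acc, tries)}
    moved = [nm for nm, t in zip(names, tries) if t]
    if moved and all(rates[nm] == 0.0 for nm in moved):
        raise RuntimeError("zero acceptance for all updated parameters")
    if sigma_hits > 0.5 * M:
        warnings.warn(
            "sigma spent most of the chain near its prior upper bound; "
            "increase sigma_max"
        )
    return PosteriorChains(
        names=names,
        theta=theta_out,
        n0=n0_out,
        mu_pi0=mupi0_out,
        seed=seed,
        burn_in=burn_in,
        accept_rate=rates,
    )


@dataclass
class PosteriorSummary:
    mean: float
    q025: float
    q975: float
    mcse_mean: float
    pmf: "object" = None  # pandas Series indexed by N


def posterior_N(chains: PosteriorChains, n: int) -> PosteriorSummary:
    """Posterior of abundance N = n + n0 from the retained n0 draws.

    The pmf estimate is Rao-Blackwellized: the Poisson(mu pi0) conditional
    pmf averaged over the post-burn-in draws of theta.
    """
    import pandas as pd

    n0 = chains.post("n0")
    mupi0 = chains.post("mu_pi0")
    N = n + n0
    kmax = int(np.quantile(n0, 0.999) + 6 * np.sqrt(mupi0.mean() + 1.0)) + 2
    ks = np.arange(kmax + 1)
    pmf = poisson.pmf(ks[None, :], mupi0[:, None]).mean(axis=0)
    return PosteriorSummary(
        mean=float(N.mean()),
        q025=float(np.quantile(N, 0.025)),
        q975=float(np.quantile(N, 0.975)),
        mcse_mean=mcse_obm(N.astype(float)),
        pmf=pd.Series(pmf, index=n + ks, name="pmf"),
    )


def posterior_N_region(
    chains: PosteriorChains,
    context,
    sub: Region | np.ndarray,
    max_draws: int = 500,
    seed: int = 0,
) -> PosteriorSummary:
    """Posterior of the number of activity centers inside a subregion of B.

    For each (thinned) posterior draw of theta, each detected individual's
    center pixel is sampled from its conditional distribution and counted
    if inside the subregion; a Poisson draw with mean equal to the thinned
    intensity integrated over the subregion adds the undetected part.
    """
    ss = context.ss
    mask = sub if isinstance(sub, np.ndarray) else ss.mask_for(sub)
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    theta_post = chains.theta[chains.burn_in :]
    idx = np.arange(theta_post.shape[0])
    if idx.size > max_draws:
        idx = np.linspace(0, idx.size - 1, max_draws).astype(int)
    context = _natural_helpers(context)
    log_a = np.log(ss.pixel_area)
    counts = np.empty(idx.size)
    for t, m in enumerate(idx):
        theta_est = context.pack(*context.unpack_natural(theta_post[m]))
        ip, _ = context.unpack(theta_est)
        lam = intensity(ss, ip)
        q = context.pixel_nondet_prob(theta_est)
        mu_sub = float((lam[mask] * q[mask]).sum() * ss.pixel_area)
        c = rng.poisson(mu_sub)
        if context.n:
            M = context.cond_loglik(theta_est) + np.log(lam)[None, :] + log_a
            W = np.exp(M - logsumexp(M, axis=1, keepdims=True))
            pr_in = W[:, mask].sum(axis=1)
            c += rng.binomial(1, np.clip(pr_in, 0.0, 1.0)).sum()
        counts[t] = c
    return PosteriorSummary(
        mean=float(counts.mean()),
        q025=float(np.quantile(counts, 0.025)),
        q975=float(np.quantile(counts, 0.975)),
        mcse_mean=mcse_obm(counts) if counts.size >= 4 else float("nan"),
    )


def mcse_obm(chain: np.ndarray, batch_size: int | None = None) -> float:
    """Monte Carlo standard error of the chain mean by overlapping batch means.

    Default batch size floor(sqrt(M)).  The OBM variance estimate is
    sigma2 = M b / ((M - b)(M - b + 1)) * sum_k (ybar_k - ybar)^2 over the
    M - b + 1 overlapping batches; the MCSE is sqrt(sigma2 / M).
    """
    x = np.asarray(chain, dtype=float)
    M = x.size
    if M < 4:
        raise ValueError("chain too short for batch means")
    b = batch_size if batch_size is not None else int(np.floor(np.sqrt(M)))
    if not (1 <= b < M):
        raise ValueError("batch size must satisfy 1 <= b < M")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    means = (csum[b:] - csum[:-b]) / b
    dev2 = (means - x.mean()) ** 2
    sigma2 = M * b / ((M - b) * (M - b + 1)) * dev2.sum()
    return float(np.sqrt(sigma2 / M))
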