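"""Independent reference computations used to check the likelihood code.

These deliberately avoid the package's vectorized implementation paths:
probabilities are accumulated by explicit loops over pixels, traps,
occasions and candidate values of the number of undetected individuals.
"""

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, multivariate_normal, norm, poisson


def hn(d, p0, sigma):
    return p0 * np.exp(-(d**2) / (2 * sigma**2))


def cond_history_prob_traps(center, traps, J, p0, sigma, y_row):
    """Product over traps of binomial pmfs, one trap at a time."""
    out = 1.0
    for k in range(traps.shape[0]):
        d = np.hypot(*(np.asarray(center) - traps[k]))
        out *= binom.pmf(y_row[k], J, hn(d, p0, sigma))
    return out


def pi0_traps_enumerated(ss, traps, J, p0, sigma, lam):
    """Intensity-weighted average of the all-zero-history probability."""
    num = den = 0.0
    for g in range(ss.G):
        q = 1.0
        for k in range(traps.shape[0]):
            d = np.hypot(*(ss.centers[g] - traps[k]))
            q *= (1 - hn(d, p0, sigma)) ** J
        num += q * lam[g] * ss.pixel_area
        den += lam[g] * ss.pixel_area
    return num / den


def loglik_traps_truncated(ss, design, det, ip_lam, y, tail_tol=1e-12):
    """Marginalized-form log-likelihood: explicit sum over the number of
    undetected individuals n0 with Poisson-binomial-thinning terms."""
    lam = ip_lam
    a = ss.pixel_area
    mu = float((lam * a).sum())
    pi0 = pi0_traps_enumerated(ss, design.traps, design.J, det.p0, det.sigma, lam)
    n = y.shape[0]
    log_h = []  # per-individual marginal history probability
    for i in range(n):
        h = 0.0
        for g in range(ss.G):
            h += (
                cond_history_prob_traps(
                    ss.centers[g], design.traps, design.J, det.p0, det.sigma, y[i]
                )
                * lam[g]
                * a
                / mu
            )
        log_h.append(np.log(h))
    terms = []
    n0 = 0
    while True:
        t = (
            poisson.logpmf(n + n0, mu)
            + gammaln(n + n0 + 1)
            - gammaln(n0 + 1)
            - gammaln(n + 1)
            + (n0 * np.log(pi0) if n0 else 0.0)
            + sum(log_h)
        )
        terms.append(t)
        # stop once past the mode and the term is negligible relative to
        # the accumulated sum
        if n0 > mu and t - logsumexp(terms) < np.log(tail_tol):
            break
        n0 += 1
        if n0 > 10000:
            raise RuntimeError("truncated sum did not converge")
    return float(logsumexp(terms))


def cond_history_density_area(center, S, J, p, sigma, w_row, u_row):
    """Survey-by-survey product of detection/location densities."""
    phi = (norm.cdf((S.xmax - center[0]) / sigma) - norm.cdf((S.xmin - center[0]) / sigma)) * (
        norm.cdf((S.ymax - center[1]) / sigma) - norm.cdf((S.ymin - center[1]) / sigma)
    )
    out = 1.0
    for j in range(J):
        if w_row[j] == 1:
            out *= p * multivariate_normal.pdf(
                u_row[j], mean=center, cov=sigma**2 * np.eye(2)
            )
        else:
            out *= 1 - p * phi
    return out


def loglik_area_truncated(ss, design, ap, lam, w, u, tail_tol=1e-12):
    a = ss.pixel_area
    mu = float((lam * a).sum())
    num = 0.0
    for g in range(ss.G):
        phi = cond_history_density_area(
            ss.centers[g], design.S, design.J, ap.p, ap.sigma,
            np.zeros(design.J, dtype=int), np.zeros((design.J, 2)),
        )
        num += phi * lam[g] * a
    pi0 = num / mu
    n = w.shape[0]
    log_h = []
    for i in range(n):
        h = 0.0
        for g in range(ss.G):
            h += (
                cond_history_density_area(
                    ss.centers[g], design.S, design.J, ap.p, ap.sigma, w[i], u[i]
                )
                * lam[g]
                * a
                / mu
            )
        log_h.append(np.log(h))
    terms = []
    n0 = 0
    while True:
        t = (
            poisson.logpmf(n + n0, mu)
            + gammaln(n + n0 + 1)
            - gammaln(n0 + 1)
            - gammaln(n + 1)
            + (n0 * np.log(pi0) if n0 else 0.0)
            + sum(log_h)
        )
        terms.append(t)
        # stop once past the mode and the term is negligible relative to
        # the accumulated sum
        if n0 > mu and t - logsumexp(terms) < np.log(tail_tol):
            break
        n0 += 1
        if n0 > 10000:
            raise RuntimeError("truncated sum did not converge")
    return float(logsumexp(terms))
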