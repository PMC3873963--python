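"""Shared maximum-likelihood machinery for the SECR observation models.

Both observation models estimate theta = (beta, detection parameters) by
maximizing a marginal likelihood of the observed capture histories.  The
optimizer works on an unconstrained scale (beta free, logit for
probabilities, log for scale parameters); variances come from the inverse
of the observed information matrix, obtained by central finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

__all__ = ["FitResult", "maximize_loglik", "numeric_hessian"]

#: transform name -> (to estimation scale, to natural scale, d natural / d est)
TRANSFORMS = {
    "identity": (lambda x: x, lambda z: z, lambda z: 1.0),
    "logit": (logit, expit, lambda z: expit(z) * (1.0 - expit(z))),
    "log": (np.log, np.exp, np.exp),
}


@dataclass
class FitResult:
    """Maximum-likelihood fit of an SECR model.

    ``theta`` holds the estimates on the estimation (unconstrained) scale;
    ``params`` the same values on the natural scale, keyed by name.
    ``vcov`` is the inverse observed information on the estimation scale
    (None when the Hessian was singular).
    """

    names: list[str]
    transforms: list[str]
    theta: np.ndarray
    loglik: float
    vcov: np.ndarray | None
    converged: bool
    context: object = field(repr=False, default=None)
    message: str = ""

    @property
    def params(self) -> dict[str, float]:
        return {
            nm: float(TRANSFORMS[tr][1](v))
            for nm, tr, v in zip(self.names, self.transforms, self.theta)
        }

    @property
    def beta(self) -> np.ndarray:
        return np.array(
            [v for nm, v in zip(self.names, self.theta) if nm.startswith("beta")]
        )

    def se(self, scale: str = "natural") -> dict[str, float]:
        """Standard errors on the natural or estimation scale (delta method)."""
        if self.vcov is None:
            raise ValueError("variance-covariance matrix unavailable")
        se_est = np.sqrt(np.clip(np.diag(self.vcov), 0.0, np.inf))
        if scale == "estimation":
            return dict(zip(self.names, se_est))
        grads = np.array(
            [TRANSFORMS[tr][2](v) for tr, v in zip(self.transforms, self.theta)]
        )
        return dict(zip(self.names, se_est * np.abs(grads)))

    def wald_ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        """Wald intervals computed on the estimation scale and back-transformed.

        For probabilities and scale parameters this yields the asymmetric
        (logit- / log-scale) intervals; for beta the usual symmetric ones.
        """
        from scipy.stats import norm

        if self.vcov is None:
            raise ValueError("variance-covariance matrix unavailable")
        z = norm.ppf(0.5 + level / 2)
        se_est = np.sqrt(np.clip(np.diag(self.vcov), 0.0, np.inf))
        out = {}
        for nm, tr, v, s in zip(self.names, self.transforms, self.theta, se_est):
            back = TRANSFORMS[tr][1]
            out[nm] = (float(back(v - z * s)), float(back(v + z * s)))
        return out

    def vcov_natural(self) -> np.ndarray:
        """Delta-method variance-covariance matrix on the natural scale."""
        if self.vcov is None:
            raise ValueError("variance-covariance matrix unavailable")
        g = np.array(
            [TRANSFORMS[tr][2](v) for tr, v in zip(self.transforms, self.theta)]
        )
        return self.vcov * np.outer(g, g)


def numeric_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian of a scalar function.

    Step is relative: h_i = step * max(1, |x_i|).
    """
    x = np.asarray(x, dtype=float)
    d = x.size
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def maximize_loglik(
    loglik: Callable[[np.ndarray], float],
    start: np.ndarray,
    names: list[str],
    transforms: list[str],
    context: object = None,
) -> FitResult:
    """Quasi-Newton maximization with numeric gradients and observed-information vcov."""

    def nll(theta: np.ndarray) -> float:
        ll = loglik(theta)
        return np.inf if not np.isfinite(ll) else -ll

    res = optimize.minimize(nll, np.asarray(start, dtype=float), method="L-BFGS-B")
    theta_hat = res.x
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"optimizer did not report convergence: {res.message}")

    vcov = None
    try:
        H = numeric_hessian(nll, theta_hat)
        vcov = np.linalg.inv(H)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
            warnings.warn("observed information is not positive definite; vcov unavailable")
            vcov = None
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; vcov unavailable")

    return FitResult(
        names=list(names),
        transforms=list(transforms),
        theta=theta_hat,
        loglik=float(-res.fun),
        vcov=vcov,
        converged=converged,
        context=context,
        message=str(res.message),
    )
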