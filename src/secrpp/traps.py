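"""SECR likelihood for recaptures at arrays of proximity detectors.

Individuals are detected at most once per occasion at each of K traps;
the count of detections of individual i at trap k over J occasions is
binomial with a half-normal (Gaussian-kernel) capture probability that
decays with the distance between the trap and the individual's activity
center.  The activity centers follow an inhomogeneous Poisson point
process over the state space B, so the observed individuals are a thinned
Poisson process and the marginal likelihood has a closed thinned-Poisson
form that is evaluated by Riemann summation over the pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, logit, logsumexp

from .fitting import FitResult, maximize_loglik
from .statespace import IntensityParams, StateSpace, intensity

__all__ = [
    "DetectionParams",
    "TrapDesign",
    "TrapCaptures",
    "halfnormal_p",
    "cond_capture_loglik",
    "pi0_traps",
    "loglik_traps",
    "fit_traps",
    "TrapsContext",
]

_P_FLOOR = 1e-300  # guards log(p) when p underflows; y>0 there is then ~impossible
_P_CEIL = 1e-16  # guards log(1-p) at p=1


@dataclass(frozen=True)
class DetectionParams:
    """Half-normal detection function parameters.

    p0 is the capture probability at distance zero; sigma the spatial
    scale (same units as the trap coordinates).
    """

    p0: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class TrapDesign:
    """K trap locations sampled over J occasions of equal duration."""

    traps: np.ndarray
    J: int

    def __post_init__(self) -> None:
        self.traps = np.atleast_2d(np.asarray(self.traps, dtype=float))
        if self.traps.shape[1] != 2:
            raise ValueError("traps must be an array of (x, y) coordinates")
        if self.J < 0:
            raise ValueError("number of occasions must be nonnegative")
        uniq = np.unique(self.traps, axis=0)
        if uniq.shape[0] != self.traps.shape[0]:
            raise ValueError("trap coordinates must be distinct")

    @property
    def K(self) -> int:
        return self.traps.shape[0]


@dataclass
class TrapCaptures:
    """n x K matrix of per-trap detection counts for the detected individuals."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y))
        if not np.issubdtype(self.y.dtype, np.integer):
            if not np.allclose(self.y, np.round(self.y)):
                raise ValueError("capture counts must be integers")
            self.y = np.round(self.y).astype(int)
        if np.any(self.y < 0):
            raise ValueError("capture counts must be nonnegative")
        if self.y.shape[0] > 0 and np.any(self.y.sum(axis=1) == 0):
            raise ValueError("every detected individual needs at least one capture")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def validate(self, design: TrapDesign) -> None:
        if self.y.shape[1] != design.K:
            raise ValueError("capture matrix columns must match number of traps")
        if np.any(self.y > design.J):
            raise ValueError("capture counts cannot exceed the number of occasions")


def halfnormal_p(d, det: DetectionParams):
    """Capture probability p0 * exp(-d^2 / (2 sigma^2)) at distance d >= 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    return det.p0 * np.exp(-(d**2) / (2.0 * det.sigma**2))


def _p_matrix(centers: np.ndarray, traps: np.ndarray, det: DetectionParams) -> np.ndarray:
    """(G, K) capture probabilities between pixel centers and traps."""
    d2 = ((centers[:, None, :] - traps[None, :, :]) ** 2).sum(axis=2)
    return det.p0 * np.exp(-d2 / (2.0 * det.sigma**2))


def _cond_loglik_matrix(
    centers: np.ndarray, design: TrapDesign, det: DetectionParams, Y: np.ndarray
) -> np.ndarray:
    """(n, G) log joint probability of each capture history given each center.

    Product over traps of binomial probabilities Bin(y_k; J, p_k(s)), with
    binomial coefficients included (log space).
    """
    J = design.J
    if np.any(Y > J):
        raise ValueError("capture counts cannot exceed the number of occasions")
    P = _p_matrix(centers, design.traps, det)
    logp = np.log(np.maximum(P, _P_FLOOR))
    log1mp = np.log1p(-np.minimum(P, 1.0 - _P_CEIL))
    Y = np.asarray(Y, dtype=float)
    const = (gammaln(J + 1) - gammaln(Y + 1) - gammaln(J - Y + 1)).sum(axis=1)
    return const[:, None] + Y @ logp.T + (J - Y) @ log1mp.T


def cond_capture_loglik(
    ss: StateSpace, design: TrapDesign, det: DetectionParams, y_row: np.ndarray
) -> np.ndarray:
    """Per-pixel log density of one capture history given the activity center."""
    y_row = np.atleast_1d(np.asarray(y_row))
    return _cond_loglik_matrix(ss.centers, design, det, y_row[None, :])[0]


def _log_q_pixel(
    centers: np.ndarray, design: TrapDesign, det: DetectionParams
) -> np.ndarray:
    """Per-pixel log probability of an all-zero history over all traps and occasions."""
    P = _p_matrix(centers, design.traps, det)
    return design.J * np.log1p(-np.minimum(P, 1.0 - _P_CEIL)).sum(axis=1)


def pi0_traps(
    ss: StateSpace,
    design: TrapDesign,
    det: DetectionParams,
    params: IntensityParams,
) -> float:
    """Probability that a population member is never detected.

    The all-zero-history probability prod_k (1 - p_k(s))^J averaged over
    the intensity-weighted distribution of activity centers.
    """
    lam = intensity(ss, params)
    q = np.exp(_log_q_pixel(ss.centers, design, det))
    w = lam * ss.pixel_area
    return float((q * w).sum() / w.sum())


def loglik_traps(
    ss: StateSpace,
    design: TrapDesign,
    det: DetectionParams,
    params: IntensityParams,
    data: TrapCaptures,
) -> float:
    """Marginal log-likelihood of the observed capture histories.

    Thinned-Poisson form: -mu (1 - pi0) + sum_i log integral_B
    [history density | s] lam(s) ds - log n!, where the integral is a
    Riemann sum over pixels.  Equivalent to summing the complete-data
    likelihood over the unknown number of undetected individuals.
    """
    data.validate(design)
    lam = intensity(ss, params)
    a = ss.pixel_area
    mu = float(lam.sum() * a)
    q = np.exp(_log_q_pixel(ss.centers, design, det))
    pi0 = float((q * lam * a).sum() / mu)
    ll = -mu * (1.0 - pi0)
    n = data.n
    if n > 0:
        M = _cond_loglik_matrix(ss.centers, design, det, data.y)
        ll += logsumexp(M + np.log(lam * a)[None, :], axis=1).sum()
        ll -= gammaln(n + 1)
    return float(ll)


class TrapsContext:
    """Bundles state space, design and data; maps the estimation-scale
    parameter vector (beta..., logit p0, log sigma) to likelihood pieces.

    This is the model object shared by the MLE fitter, the empirical Bayes
    abundance estimator and the MCMC sampler.
    """

    kind = "traps"

    def __init__(self, ss: StateSpace, design: TrapDesign, data: TrapCaptures):
        data.validate(design)
        self.ss = ss
        self.design = design
        self.data = data
        p = ss.X.shape[1]
        self.names = [f"beta{i}" for i in range(p)] + ["p0", "sigma"]
        self.transforms = ["identity"] * p + ["logit", "log"]
        self.n_beta = p
        self._cache: dict = {}
        # distance matrix and binomial coefficients never change across
        # likelihood evaluations; precompute them once
        self._d2 = ((ss.centers[:, None, :] - design.traps[None, :, :]) ** 2).sum(axis=2)
        Yf = data.y.astype(float)
        self._Yf = Yf
        J = design.J
        self._logbinom = (gammaln(J + 1) - gammaln(Yf + 1) - gammaln(J - Yf + 1)).sum(axis=1)

    def _detection_pieces(self, det: DetectionParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(cond loglik matrix, per-pixel all-zero-history prob, row logsumexp);
        cached on (p0, sigma) so intensity-only updates skip the kernels."""
        key = (det.p0, det.sigma)
        hit = self._cache.get(key)
        if hit is None:
            P = det.p0 * np.exp(-self._d2 / (2.0 * det.sigma**2))
            logp = np.log(np.maximum(P, _P_FLOOR))
            log1mp = np.log1p(-np.minimum(P, 1.0 - _P_CEIL))
            J = self.design.J
            M = self._logbinom[:, None] + self._Yf @ logp.T + (J - self._Yf) @ log1mp.T
            q = np.exp(J * log1mp.sum(axis=1))
            rowlse = logsumexp(M, axis=1) if self.data.n else np.zeros(0)
            if len(self._cache) > 8:
                self._cache.clear()
            self._cache[key] = hit = (M, q, rowlse)
        return hit

    @property
    def n(self) -> int:
        return self.data.n

    def unpack(self, theta: np.ndarray) -> tuple[IntensityParams, DetectionParams]:
        beta = np.asarray(theta[: self.n_beta], dtype=float)
        p0 = float(expit(theta[self.n_beta]))
        sigma = float(np.exp(theta[self.n_beta + 1]))
        return IntensityParams(beta), DetectionParams(p0, sigma)

    def pack(self, params: IntensityParams, det: DetectionParams) -> np.ndarray:
        return np.concatenate(
            [params.beta, [logit(det.p0), np.log(det.sigma)]]
        )

    def loglik(self, theta: np.ndarray) -> float:
        ip, det = self.unpack(theta)
        M, q, rowlse = self._detection_pieces(det)
        a = self.ss.pixel_area
        n = self.data.n
        if self.n_beta == 1:
            # homogeneous intensity: lam factors out of every pixel sum
            lam0 = float(np.exp(theta[0]))
            ll = -lam0 * a * self.ss.G + lam0 * a * float(q.sum())
            if n:
                ll += n * np.log(lam0 * a) + float(rowlse.sum())
                ll -= float(gammaln(n + 1))
            return ll
        lam = intensity(self.ss, ip)
        mu = float(lam.sum() * a)
        ll = -mu + float((q * lam * a).sum())
        if n:
            ll += float(logsumexp(M + np.log(lam * a)[None, :], axis=1).sum())
            ll -= float(gammaln(n + 1))
        return ll

    def mu_pi0(self, theta: np.ndarray) -> tuple[float, float]:
        ip, det = self.unpack(theta)
        lam = intensity(self.ss, ip)
        a = self.ss.pixel_area
        mu = float(lam.sum() * a)
        q = self._detection_pieces(det)[1]
        return mu, float((q * lam * a).sum() / mu)

    def pixel_nondet_prob(self, theta: np.ndarray) -> np.ndarray:
        """Per-pixel probability of an all-zero history (thinning survival)."""
        _, det = self.unpack(theta)
        return self._detection_pieces(det)[1]

    def cond_loglik(self, theta: np.ndarray) -> np.ndarray:
        """(n, G) log density of each observed history given each pixel."""
        _, det = self.unpack(theta)
        return self._detection_pieces(det)[0]

    def default_start(self) -> np.ndarray:
        ss, design, y = self.ss, self.design, self.data.y
        J, n = max(design.J, 1), self.data.n
        p0 = np.clip(y.max(axis=1).mean() / J if n else 0.1, 0.02, 0.9)
        if design.K > 1:
            d = np.sqrt(
                ((design.traps[:, None, :] - design.traps[None, :, :]) ** 2).sum(-1)
            )
            np.fill_diagonal(d, np.inf)
            sigma = 0.5 * d.min(axis=1).mean()
        else:
            sigma = 0.25 * min(ss.region.width, ss.region.height)
        beta = np.zeros(self.n_beta)
        beta[0] = np.log(max(n, 1) / (0.5 * ss.region.area))
        return np.concatenate([beta, [logit(p0), np.log(sigma)]])


def fit_traps(
    ss: StateSpace,
    design: TrapDesign,
    data: TrapCaptures,
    start: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the trapping-array model.

    Estimation is on the unconstrained scale (beta free, logit p0, log
    sigma); the variance-covariance matrix is the inverse observed
    information at the maximum, by central finite differences.
    """
    if data.n < 1:
        raise ValueError("at least one detected individual is required")
    ctx = TrapsContext(ss, design, data)
    x0 = np.asarray(start, dtype=float) if start is not None else ctx.default_start()
    return maximize_loglik(ctx.loglik, x0, ctx.names, ctx.transforms, context=ctx)
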