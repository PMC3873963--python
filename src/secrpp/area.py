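"""SECR likelihood for recapture locations observed in area searches.

A rectangular plot S inside the state space B is searched J times.  An
individual's location on each occasion is a bivariate normal draw around
its activity center (scale sigma, independent axes); an individual whose
location falls inside S is detected with probability p.  Detected
individuals contribute the density of their observed locations; the
non-detection probability integrates the movement kernel over S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, logit, logsumexp, ndtr

from .fitting import FitResult, maximize_loglik
from .statespace import IntensityParams, Region, StateSpace, intensity

__all__ = [
    "AreaDesign",
    "AreaParams",
    "AreaCaptures",
    "prob_in_S",
    "pi0_area",
    "cond_area_loglik",
    "loglik_area",
    "fit_area",
    "AreaContext",
]


@dataclass
class AreaDesign:
    """Search plot S (inside B) surveyed uniformly on J occasions."""

    S: Region
    J: int

    def __post_init__(self) -> None:
        if self.J < 0:
            raise ValueError("number of occasions must be nonnegative")


@dataclass(frozen=True)
class AreaParams:
    """Per-survey detection probability p and bivariate-normal movement scale sigma."""

    p: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class AreaCaptures:
    """Detection indicators w (n x J) and capture locations u (n x J x 2).

    Locations are defined (finite) exactly where w == 1 and must lie
    inside the search plot.
    """

    w: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.atleast_2d(np.asarray(self.w)).astype(int)
        self.u = np.asarray(self.u, dtype=float)
        if set(np.unique(self.w)) - {0, 1}:
            raise ValueError("detection indicators must be 0/1")
        if self.u.shape != self.w.shape + (2,):
            raise ValueError("u must have shape (n, J, 2)")
        if self.w.shape[0] > 0 and np.any(self.w.sum(axis=1) == 0):
            raise ValueError("every retained individual needs at least one detection")
        det = self.w == 1
        if np.any(~np.isfinite(self.u[det])):
            raise ValueError("capture location missing for a detection")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def J(self) -> int:
        return self.w.shape[1]

    def validate(self, design: AreaDesign) -> None:
        if self.J != design.J:
            raise ValueError("capture matrix columns must match number of occasions")
        det = self.w == 1
        if det.any() and not np.all(design.S.contains(self.u[det])):
            raise ValueError("capture locations must lie inside the search plot")


def prob_in_S(s: np.ndarray, S: Region, sigma: float) -> np.ndarray:
    """Probability that a bivariate-normal location around center(s) s lies in S.

    With independent axes the rectangle probability factorizes into
    products of univariate normal CDF differences.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s = np.asarray(s, dtype=float)
    scalar = s.ndim == 1
    s = np.atleast_2d(s)
    px = ndtr((S.xmax - s[:, 0]) / sigma) - ndtr((S.xmin - s[:, 0]) / sigma)
    py = ndtr((S.ymax - s[:, 1]) / sigma) - ndtr((S.ymin - s[:, 1]) / sigma)
    out = px * py
    return float(out[0]) if scalar else out


def pi0_area(
    ss: StateSpace,
    design: AreaDesign,
    ap: AreaParams,
    params: IntensityParams,
) -> float:
    """Probability that a population member is never detected in J searches."""
    lam = intensity(ss, params)
    phi = prob_in_S(ss.centers, design.S, ap.sigma)
    q = (1.0 - ap.p * phi) ** design.J
    w = lam * ss.pixel_area
    return float((q * w).sum() / w.sum())


def _cond_loglik_matrix(
    centers: np.ndarray, design: AreaDesign, ap: AreaParams, w: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """(n, G) log joint density of each individual's detections and locations
    given each candidate activity-center pixel."""
    n, J = w.shape
    G = centers.shape[0]
    phi = prob_in_S(centers, design.S, ap.sigma)
    log_q1 = np.log1p(-np.minimum(ap.p * phi, 1.0 - 1e-16))
    ndet = w.sum(axis=1)
    M = np.outer(J - ndet, log_q1)
    M += (ndet * np.log(ap.p))[:, None]
    det_i, det_j = np.nonzero(w == 1)
    if det_i.size:
        pts = u[det_i, det_j]  # (m, 2)
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)  # (m, G)
        logphi2 = -np.log(2.0 * np.pi * ap.sigma**2) - d2 / (2.0 * ap.sigma**2)
        # det_i is sorted (row-major scan); sum each individual's detections
        has = ndet > 0
        bounds = np.concatenate([[0], np.cumsum(ndet[has])[:-1]])
        M[has] += np.add.reduceat(logphi2, bounds, axis=0)
    return M


def cond_area_loglik(
    ss: StateSpace,
    design: AreaDesign,
    ap: AreaParams,
    w_row: np.ndarray,
    u_row: np.ndarray,
) -> np.ndarray:
    """Per-pixel log density of one individual's history (detections and locations)."""
    w_row = np.atleast_1d(np.asarray(w_row)).astype(int)
    u_row = np.asarray(u_row, dtype=float)
    det = w_row == 1
    if det.any() and not np.all(design.S.contains(u_row[det])):
        raise ValueError("capture locations must lie inside the search plot")
    return _cond_loglik_matrix(ss.centers, design, ap, w_row[None, :], u_row[None, :])[0]


def loglik_area(
    ss: StateSpace,
    design: AreaDesign,
    ap: AreaParams,
    params: IntensityParams,
    data: AreaCaptures,
) -> float:
    """Marginal log-likelihood of the observed area-search data.

    Same thinned-Poisson structure as the trapping-array model:
    -mu (1 - pi0) + sum_i log Riemann-sum_g exp(cond loglik) lam_g a - log n!.
    """
    data.validate(design)
    lam = intensity(ss, params)
    a = ss.pixel_area
    mu = float(lam.sum() * a)
    phi = prob_in_S(ss.centers, design.S, ap.sigma)
    pi0 = float((((1.0 - ap.p * phi) ** design.J) * lam * a).sum() / mu)
    ll = -mu * (1.0 - pi0)
    if data.n > 0:
        M = _cond_loglik_matrix(ss.centers, design, ap, data.w, data.u)
        ll += logsumexp(M + np.log(lam * a)[None, :], axis=1).sum()
        ll -= gammaln(data.n + 1)
    return float(ll)


class AreaContext:
    """Estimation-scale parameter mapping and likelihood pieces for the
    area-search model; same interface as TrapsContext."""

    kind = "area"

    def __init__(self, ss: StateSpace, design: AreaDesign, data: AreaCaptures):
        data.validate(design)
        self.ss = ss
        self.design = design
        self.data = data
        p = ss.X.shape[1]
        self.names = [f"beta{i}" for i in range(p)] + ["p", "sigma"]
        self.transforms = ["identity"] * p + ["logit", "log"]
        self.n_beta = p
        self._cache: dict = {}
        # The log bivariate-normal kernel is linear in the squared distance,
        # so each individual's detection term reduces to sufficient
        # statistics: its detection count and the per-pixel sum of squared
        # distances from its capture locations.  Precompute both.
        self._ndet = data.w.sum(axis=1)
        det_i, det_j = np.nonzero(data.w == 1)
        if det_i.size:
            pts = data.u[det_i, det_j]
            c = ss.centers
            d2 = (
                (pts**2).sum(axis=1)[:, None]
                + (c**2).sum(axis=1)[None, :]
                - 2.0 * pts @ c.T
            )
            has = self._ndet > 0
            bounds = np.concatenate([[0], np.cumsum(self._ndet[has])[:-1]])
            self._sumd2 = np.zeros((data.n, ss.G))
            self._sumd2[has] = np.add.reduceat(d2, bounds, axis=0)
        else:
            self._sumd2 = np.zeros((data.n, ss.G))

    def _detection_pieces(self, ap: AreaParams) -> tuple[np.ndarray, np.ndarray]:
        """(cond loglik matrix, per-pixel never-detected prob) cached on (p, sigma)."""
        key = (ap.p, ap.sigma)
        hit = self._cache.get(key)
        if hit is None:
            phi = prob_in_S(self.ss.centers, self.design.S, ap.sigma)
            log_q1 = np.log1p(-np.minimum(ap.p * phi, 1.0 - 1e-16))
            ndet = self._ndet
            M = np.outer(self.design.J - ndet, log_q1)
            M += (ndet * (np.log(ap.p) - np.log(2.0 * np.pi * ap.sigma**2)))[:, None]
            M -= self._sumd2 / (2.0 * ap.sigma**2)
            q = (1.0 - ap.p * phi) ** self.design.J
            rowlse = logsumexp(M, axis=1) if self.data.n else np.zeros(0)
            if len(self._cache) > 8:
                self._cache.clear()
            self._cache[key] = hit = (M, q, rowlse)
        return hit

    @property
    def n(self) -> int:
        return self.data.n

    def unpack(self, theta: np.ndarray) -> tuple[IntensityParams, AreaParams]:
        beta = np.asarray(theta[: self.n_beta], dtype=float)
        p = float(expit(theta[self.n_beta]))
        sigma = float(np.exp(theta[self.n_beta + 1]))
        return IntensityParams(beta), AreaParams(p, sigma)

    def pack(self, params: IntensityParams, ap: AreaParams) -> np.ndarray:
        return np.concatenate([params.beta, [logit(ap.p), np.log(ap.sigma)]])

    def loglik(self, theta: np.ndarray) -> float:
        ip, ap = self.unpack(theta)
        M, q, rowlse = self._detection_pieces(ap)
        a = self.ss.pixel_area
        n = self.data.n
        if self.n_beta == 1:
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
        ip, ap = self.unpack(theta)
        lam = intensity(self.ss, ip)
        a = self.ss.pixel_area
        mu = float(lam.sum() * a)
        q = self._detection_pieces(ap)[1]
        return mu, float((q * lam * a).sum() / mu)

    def pixel_nondet_prob(self, theta: np.ndarray) -> np.ndarray:
        _, ap = self.unpack(theta)
        return self._detection_pieces(ap)[1]

    def cond_loglik(self, theta: np.ndarray) -> np.ndarray:
        _, ap = self.unpack(theta)
        return self._detection_pieces(ap)[0]

    def default_start(self) -> np.ndarray:
        w, S = self.data.w, self.design.S
        J = max(self.design.J, 1)
        p = np.clip(w.sum() / (self.data.n * J) if self.data.n else 0.3, 0.05, 0.9)
        det = self.data.w == 1
        pts = self.data.u[det]
        if pts.shape[0] >= 4:
            ids = np.repeat(np.arange(self.data.n), self.data.w.sum(axis=1))
            resid = pts - np.array(
                [pts[ids == i].mean(axis=0) for i in range(self.data.n)]
            )[ids]
            sigma = max(float(resid.std()), 0.05 * min(S.width, S.height))
        else:
            sigma = 0.25 * min(S.width, S.height)
        beta = np.zeros(self.n_beta)
        beta[0] = np.log(max(self.data.n, 1) / (0.75 * S.area))
        return np.concatenate([beta, [logit(p), np.log(sigma)]])


def fit_area(
    ss: StateSpace,
    design: AreaDesign,
    data: AreaCaptures,
    start: np.ndarray | None = None,
    buffer_warn: float = 5.0,
) -> FitResult:
    """Maximum-likelihood fit of the area-search model.

    Warns when the buffer between the plot and the state-space boundary is
    thinner than ``buffer_warn`` times the estimated movement scale (the
    likelihood assumes locations stay inside B).
    """
    import warnings

    if data.n < 1:
        raise ValueError("at least one detected individual is required")
    ctx = AreaContext(ss, design, data)
    x0 = np.asarray(start, dtype=float) if start is not None else ctx.default_start()
    fit = maximize_loglik(ctx.loglik, x0, ctx.names, ctx.transforms, context=ctx)
    sigma_hat = fit.params["sigma"]
    S, B = design.S, ss.region
    margin = min(S.xmin - B.xmin, B.xmax - S.xmax, S.ymin - B.ymin, B.ymax - S.ymax)
    if margin < buffer_warn * sigma_hat:
        warnings.warn(
            f"buffer around the search plot ({margin:.3g}) is less than "
            f"{buffer_warn:g} estimated movement scales ({buffer_warn * sigma_hat:.3g}); "
            "consider enlarging the state space"
        )
    return fit
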