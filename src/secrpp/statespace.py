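"""Discretized state space for Poisson point-process SECR models.

The region B containing all activity centers is represented as a regular
lattice of square pixels.  All marginal likelihoods integrate over B by a
midpoint Riemann sum, so the pixel centers, the pixel area and the
per-pixel covariate design matrix defined here are the common currency of
every model in this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Region",
    "Raster",
    "IntensityParams",
    "StateSpace",
    "build_grid",
    "intensity",
    "mu_region",
    "center_density",
    "refine",
]


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle in user-declared planar units (km or m)."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("region must have positive width and height")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized point-in-rectangle test; pts has shape (..., 2)."""
        pts = np.asarray(pts, dtype=float)
        return (
            (pts[..., 0] >= self.xmin)
            & (pts[..., 0] <= self.xmax)
            & (pts[..., 1] >= self.ymin)
            & (pts[..., 1] <= self.ymax)
        )

    def buffered(self, b: float) -> "Region":
        return Region(self.xmin - b, self.xmax + b, self.ymin - b, self.ymax + b)


@dataclass
class Raster:
    """Gridded scalar field sampled at regular cell centers.

    ``x`` and ``y`` are ascending 1-d coordinate vectors of cell centers and
    ``values`` has shape ``(len(y), len(x))`` (row i corresponds to y[i]).
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.y.size, self.x.size):
            raise ValueError("raster values shape must be (len(y), len(x))")
        if self.x.size > 1 and np.any(np.diff(self.x) <= 0):
            raise ValueError("raster x coordinates must be strictly ascending")
        if self.y.size > 1 and np.any(np.diff(self.y) <= 0):
            raise ValueError("raster y coordinates must be strictly ascending")

    def cell_size(self) -> tuple[float, float]:
        dx = float(np.diff(self.x).mean()) if self.x.size > 1 else np.inf
        dy = float(np.diff(self.y).mean()) if self.y.size > 1 else np.inf
        return dx, dy

    def covers(self, region: Region) -> bool:
        dx, dy = self.cell_size()
        hx = dx / 2 if np.isfinite(dx) else np.inf
        hy = dy / 2 if np.isfinite(dy) else np.inf
        return (
            self.x.min() - hx <= region.xmin
            and self.x.max() + hx >= region.xmax
            and self.y.min() - hy <= region.ymin
            and self.y.max() + hy >= region.ymax
        )

    def sample_nearest(self, pts: np.ndarray) -> np.ndarray:
        """Value of the nearest raster cell for each point (n, 2)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        ix = np.abs(pts[:, 0][:, None] - self.x[None, :]).argmin(axis=1)
        iy = np.abs(pts[:, 1][:, None] - self.y[None, :]).argmin(axis=1)
        return self.values[iy, ix]


@dataclass(frozen=True)
class IntensityParams:
    """Coefficients beta of the log-linear intensity log lam(s) = x(s)'beta."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(b)):
            raise ValueError("intensity coefficients must be finite")
        object.__setattr__(self, "beta", b)


@dataclass
class StateSpace:
    """Regular pixel lattice over a rectangular region B.

    Attributes
    ----------
    region : Region
        The rectangle B.
    pixel_width : float
        Side length of the square pixels.
    centers : ndarray, shape (G, 2)
        Pixel midpoints.
    pixel_area : float
        Area of one pixel (pixel_width squared).
    X : ndarray, shape (G, p)
        Per-pixel covariate design matrix; column 0 is the constant 1.
        Covariate columns are powers of the standardized habitat value.
    cov_mean, cov_sd : float
        Standardization applied to the raw covariate (identity if none).
    """

    region: Region
    pixel_width: float
    centers: np.ndarray
    pixel_area: float
    X: np.ndarray
    nx: int
    ny: int
    cov_mean: float = 0.0
    cov_sd: float = 1.0
    raster: Raster | None = field(default=None, repr=False)
    degree: int = 0

    @property
    def G(self) -> int:
        return self.centers.shape[0]

    def standardize(self, raw: np.ndarray) -> np.ndarray:
        """Map raw covariate values onto the scale used in ``X``."""
        return (np.asarray(raw, dtype=float) - self.cov_mean) / self.cov_sd

    def design_row(self, raw: np.ndarray) -> np.ndarray:
        """Design matrix rows for raw covariate values (predictions)."""
        if self.degree < 1:
            raise ValueError("state space has no habitat covariate")
        v = self.standardize(raw)
        return np.column_stack([v**k for k in range(self.degree + 1)])

    def mask_for(self, sub: Region) -> np.ndarray:
        """Boolean pixel mask for a rectangular subregion of B."""
        r = self.region
        if not (
            sub.xmin >= r.xmin - 1e-9
            and sub.xmax <= r.xmax + 1e-9
            and sub.ymin >= r.ymin - 1e-9
            and sub.ymax <= r.ymax + 1e-9
        ):
            raise ValueError("subregion extends outside the state space")
        return sub.contains(self.centers)


def build_grid(
    region: Region,
    pixel_width: float,
    covariate_raster: Raster | None = None,
    degree: int = 1,
) -> StateSpace:
    """Discretize ``region`` into square pixels of side ``pixel_width``.

    The lattice is floor-based: ``nx = floor(width / pixel_width)`` columns
    with centers at ``xmin + (i + 1/2) * pixel_width`` (a sliver of the
    region may be left uncovered when the side is not an exact multiple of
    the pixel width; total covered area stays within one pixel row of the
    region's area).

    When a covariate raster is supplied, its value at each pixel center is
    looked up from the nearest raster cell, standardized to mean 0 and unit
    variance over the grid, and expanded to polynomial columns
    ``1, v, ..., v**degree``.
    """
    if pixel_width <= 0:
        raise ValueError("pixel_width must be positive")
    if pixel_width > min(region.width, region.height) + 1e-12:
        raise ValueError("pixel_width exceeds the smallest region side")

    nx = int(np.floor(region.width / pixel_width + 1e-9))
    ny = int(np.floor(region.height / pixel_width + 1e-9))
    cx = region.xmin + (np.arange(nx) + 0.5) * pixel_width
    cy = region.ymin + (np.arange(ny) + 0.5) * pixel_width
    gx, gy = np.meshgrid(cx, cy)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    a = pixel_width**2

    cov_mean, cov_sd = 0.0, 1.0
    if covariate_raster is None:
        X = np.ones((centers.shape[0], 1))
        degree = 0
    else:
        if not covariate_raster.covers(region):
            raise ValueError("covariate raster does not cover the region")
        raw = covariate_raster.sample_nearest(centers)
        cov_mean = float(raw.mean())
        sd = float(raw.std())
        cov_sd = sd if sd > 0 else 1.0
        v = (raw - cov_mean) / cov_sd
        X = np.column_stack([v**k for k in range(degree + 1)])

    return StateSpace(
        region=region,
        pixel_width=pixel_width,
        centers=centers,
        pixel_area=a,
        X=X,
        nx=nx,
        ny=ny,
        cov_mean=cov_mean,
        cov_sd=cov_sd,
        raster=covariate_raster,
        degree=degree,
    )


def refine(ss: StateSpace, factor: int = 2) -> StateSpace:
    """Rebuild the grid at ``pixel_width / factor`` (grid-adequacy checks)."""
    return build_grid(
        ss.region,
        ss.pixel_width / factor,
        covariate_raster=ss.raster,
        degree=ss.degree if ss.raster is not None else 1,
    )


def intensity(ss: StateSpace, params: IntensityParams) -> np.ndarray:
    """Per-pixel intensity lam_g = exp(x(s_g)' beta); strictly positive."""
    beta = params.beta
    if beta.size != ss.X.shape[1]:
        raise ValueError(
            f"beta has length {beta.size}, design matrix has {ss.X.shape[1]} columns"
        )
    return np.exp(ss.X @ beta)


def mu_region(
    ss: StateSpace,
    params: IntensityParams,
    mask: np.ndarray | None = None,
) -> float:
    """Expected number of activity centers: Riemann sum of lam over pixels."""
    lam = intensity(ss, params)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (ss.G,):
            raise ValueError("mask must have one entry per pixel")
        lam = lam[mask]
    return float(lam.sum() * ss.pixel_area)


def center_density(ss: StateSpace, params: IntensityParams) -> np.ndarray:
    """Per-pixel probability lam_g a / mu of a single activity center.

    Homogeneous intensity gives the uniform distribution 1/G; any common
    scaling of the intensity cancels.
    """
    lam = intensity(ss, params)
    w = lam * ss.pixel_area
    return w / w.sum()


def check_grid_stability(loglik_fn, ss: StateSpace, tol: float = 1e-2) -> float:
    """Difference in a log-likelihood functional between ss and its refinement.

    ``loglik_fn`` maps a StateSpace to a scalar.  Warns when the change
    exceeds ``tol``, signalling that the pixel width is too coarse.
    """
    d = abs(loglik_fn(refine(ss)) - loglik_fn(ss))
    if d > tol:
        warnings.warn(
            f"log-likelihood changed by {d:.4g} when halving pixel width; "
            "grid may be too coarse",
            stacklevel=2,
        )
    return d
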