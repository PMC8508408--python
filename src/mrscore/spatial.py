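"""Spatial methods: 2-D Gaussian kernel density estimation, geographically
weighted regression (GWR) with AICc bandwidth selection, and a Moran's I
permutation test for residual spatial randomness.

All three operate on planar coordinates. For geographic data project
lon/lat to metres first (see :func:`project_cities`); the GWR distance-decay
kernel is w_ij = exp(-d_ij^2 / b^2) — note the absence of the conventional
1/2 factor — with a fixed (non-adaptive) bandwidth b in the same units as
the coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geo import aeqd_project
from .errors import ConfigurationError, NumericalError

logger = logging.getLogger(__name__)


def project_cities(lon, lat) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat degrees to planar x/y metres (azimuthal equidistant
    about the point-set centroid)."""
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    return aeqd_project(lon, lat, float(lon.mean()), float(lat.mean()))


# ---------------------------------------------------------------- KDE

@dataclass
class KdeSurface:
    """Gridded density surface. ``density[r, c]`` is the estimate at
    x = x0 + (c + 0.5) * cell, y = y0 + (r + 0.5) * cell (cell centres,
    row 0 at the bottom)."""

    x0: float
    y0: float
    cell: float
    density: np.ndarray
    bandwidth: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.density.shape

    def integral(self) -> float:
        return float(self.density.sum() * self.cell ** 2)

    def grid_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.density.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell
        return xs, ys

    def write_ascii_grid(self, path) -> None:
        """ESRI ASCII grid (text raster, row 0 at the top)."""
        ny, nx = self.density.shape
        header = (f"ncols {nx}\nnrows {ny}\nxllcorner {self.x0}\n"
                  f"yllcorner {self.y0}\ncellsize {self.cell}\n"
                  f"NODATA_value -9999\n")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            np.savetxt(fh, self.density[::-1], fmt="%.8e")


def kde_at(points: np.ndarray, queries: np.ndarray, h: float,
           local_count_normalization: bool = False) -> np.ndarray:
    """Gaussian kernel density at arbitrary query locations.

    f(p) = sum_i 1/(n h^2) * phi((p - p_i)/h), phi the bivariate standard
    normal density, n the total point count. With
    ``local_count_normalization`` n is instead the number of points within
    distance h of p (a non-standard variant; the resulting surface is no
    longer a probability density).
    """
    if h <= 0:
        raise ConfigurationError("bandwidth h must be positive")
    points = np.atleast_2d(np.asarray(points, float))
    queries = np.atleast_2d(np.asarray(queries, float))
    if points.size == 0:
        raise ConfigurationError("at least one point is required")
    out = np.empty(len(queries))
    chunk = max(1, int(2e7) // max(len(points), 1))
    for start in range(0, len(queries), chunk):
        q = queries[start:start + chunk]
        d2 = ((q[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
        kern = np.exp(-d2 / (2.0 * h * h)) / (2.0 * np.pi * h * h)
        if local_count_normalization:
            n_loc = (d2 <= h * h).sum(axis=1)
            out[start:start + chunk] = np.where(
                n_loc > 0, kern.sum(axis=1) / np.maximum(n_loc, 1), 0.0)
        else:
            out[start:start + chunk] = kern.sum(axis=1) / len(points)
    return out


def kde(points: np.ndarray, h: float, x0: float | None = None,
        y0: float | None = None, cell: float | None = None,
        nx: int = 128, ny: int = 128, pad: float = 4.0,
        local_count_normalization: bool = False) -> KdeSurface:
    """Evaluate the kernel density on a regular grid.

    By default the grid covers the point bounding box padded by ``pad``
    bandwidths (enough for the numeric integral to come out ~1).
    """
    points = np.atleast_2d(np.asarray(points, float))
    if h <= 0:
        raise ConfigurationError("bandwidth h must be positive")
    if x0 is None or y0 is None or cell is None:
        xmin, ymin = points.min(axis=0) - pad * h
        xmax, ymax = points.max(axis=0) + pad * h
        # resolve at least half a bandwidth per cell or the Riemann sum
        # under-counts sharp peaks; cap the grid to keep work bounded
        cell = min(max(xmax - xmin, ymax - ymin) / max(nx, ny), h / 2.0)
        if max(xmax - xmin, ymax - ymin) / cell > 1024:
            cell = max(xmax - xmin, ymax - ymin) / 1024
        x0, y0 = float(xmin), float(ymin)
        nx = int(np.ceil((xmax - xmin) / cell))
        ny = int(np.ceil((ymax - ymin) / cell))
    xs = x0 + (np.arange(nx) + 0.5) * cell
    ys = y0 + (np.arange(ny) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys)
    queries = np.column_stack([gx.ravel(), gy.ravel()])
    dens = kde_at(points, queries, h,
                  local_count_normalization=local_count_normalization)
    return KdeSurface(x0=x0, y0=y0, cell=float(cell),
                      density=dens.reshape(ny, nx), bandwidth=h)


# ---------------------------------------------------------------- GWR

@dataclass
class GwrFit:
    """Result of a geographically weighted regression at one bandwidth."""

    bandwidth: float
    coefficients: np.ndarray        # (n, k+1): intercept first
    fitted: np.ndarray
    residuals: np.ndarray
    std_residuals: np.ndarray
    local_r2: np.ndarray
    hat_diag: np.ndarray
    trace_s: float
    aicc: float
    sigma2: float
    n_clipped_r2: int = 0
    moran: "MoranResult | None" = None
    columns: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.fitted)

    @property
    def effective_params(self) -> float:
        return self.trace_s

    def summary(self) -> dict[str, float]:
        return {
            "bandwidth": self.bandwidth,
            "aicc": self.aicc,
            "effective_params": self.trace_s,
            "mean_local_r2": float(self.local_r2.mean()),
            "sum_std_residuals": float(self.std_residuals.sum()),
        }


def _design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    return np.column_stack([np.ones(len(x)), x])


def gwr_fit(coords: np.ndarray, y: np.ndarray, x: np.ndarray,
            bandwidth: float, column_names: tuple[str, ...] = ()) -> GwrFit:
    """Fit y on covariates x with location-specific coefficients.

    At each location i the coefficients solve the weighted least-squares
    problem with Gaussian decay weights w_ij = exp(-d_ij^2 / b^2). Also
    computed per location: fitted value, residual, internally studentized
    residual (residual / (sigma * sqrt(1 - S_ii))), and the local weighted
    R^2; globally: the hat-matrix trace and the corrected AIC.
    """
    if bandwidth <= 0:
        raise ConfigurationError("bandwidth must be positive")
    coords = np.asarray(coords, float)
    y = np.asarray(y, float)
    design = _design(x)
    n, k = design.shape
    if n < k + 1:
        raise ConfigurationError(f"need at least {k + 1} observations")

    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    w_all = np.exp(-d2 / (bandwidth * bandwidth))

    betas = np.empty((n, k))
    hat_diag = np.empty(n)
    local_r2 = np.empty(n)
    n_clipped = 0
    for i in range(n):
        w = w_all[i]
        xtw = design.T * w
        xtwx = xtw @ design
        try:
            xtwx_inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"singular local design at location index {i}") from exc
        cond = np.linalg.cond(xtwx)
        if cond > 1e12:
            raise NumericalError(
                f"effectively singular local fit at location index {i} "
                f"(condition number {cond:.2e}); increase the bandwidth")
        beta = xtwx_inv @ (xtw @ y)
        betas[i] = beta
        hat_diag[i] = design[i] @ xtwx_inv @ xtw[:, i]
        yhat_local = design @ beta
        ybar_w = np.average(y, weights=w)
        tss = np.sum(w * (y - ybar_w) ** 2)
        rss = np.sum(w * (y - yhat_local) ** 2)
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        if r2 < 0.0 or r2 > 1.0:
            n_clipped += 1
            r2 = min(max(r2, 0.0), 1.0)
        local_r2[i] = r2

    fitted = np.einsum("ij,ij->i", design, betas)
    residuals = y - fitted
    trace_s = float(hat_diag.sum())
    rss = float(residuals @ residuals)
    sigma2 = rss / n
    denom = np.sqrt(np.clip(1.0 - hat_diag, 1e-12, None))
    # a numerically perfect fit leaves only rounding error in the residuals;
    # studentizing by a ~0 sigma would amplify that noise to O(1)
    y_scale = float(np.var(y)) if np.var(y) > 0 else 1.0
    perfect = sigma2 <= 1e-24 * y_scale
    std_resid = np.zeros(n) if perfect \
        else residuals / (math.sqrt(sigma2) * denom)
    aicc = _aicc(n, sigma2, trace_s)
    if n_clipped:
        logger.warning("clipped local R^2 at %d of %d locations", n_clipped, n)
    return GwrFit(bandwidth=float(bandwidth), coefficients=betas,
                  fitted=fitted, residuals=residuals, std_residuals=std_resid,
                  local_r2=local_r2, hat_diag=hat_diag, trace_s=trace_s,
                  aicc=aicc, sigma2=sigma2, n_clipped_r2=n_clipped,
                  columns=("intercept",) + (tuple(column_names) or tuple(
                      f"x{j}" for j in range(1, k))))


def _aicc(n: int, sigma2: float, trace_s: float) -> float:
    """Corrected AIC for locally weighted regression with effective
    parameter count = trace of the hat matrix."""
    if sigma2 <= 0:
        return -math.inf
    denom = n - 2.0 - trace_s
    if denom <= 0:
        return math.inf
    return (2.0 * n * math.log(math.sqrt(sigma2)) + n * math.log(2.0 * math.pi)
            + n * (n + trace_s) / denom)


def select_bandwidth(coords: np.ndarray, y: np.ndarray, x: np.ndarray,
                     b_min: float, b_max: float, rel_tol: float = 1e-3,
                     n_grid: int = 12) -> tuple[float, pd.DataFrame]:
    """Minimize AICc over bandwidth by coarse log-grid + golden-section.

    Returns (best bandwidth, evaluation trace sorted by bandwidth). If the
    coarse trace is not unimodal a warning is logged and the global trace
    minimum still wins. Deterministic given the range and tolerance.
    """
    if not (0 < b_min < b_max):
        raise ConfigurationError("need 0 < b_min < b_max")
    cache: dict[float, float] = {}

    def aicc_of(b: float) -> float:
        if b not in cache:
            try:
                cache[b] = gwr_fit(coords, y, x, b).aicc
            except NumericalError:
                cache[b] = math.inf
        return cache[b]

    grid = np.exp(np.linspace(math.log(b_min), math.log(b_max), n_grid))
    vals = np.array([aicc_of(float(b)) for b in grid])
    finite = np.where(np.isfinite(vals))[0]
    if finite.size == 0:
        raise NumericalError("AICc undefined over the whole bandwidth range")
    j = int(finite[np.argmin(vals[finite])])
    signs = np.sign(np.diff(vals[finite]))
    if np.count_nonzero(np.diff(signs[signs != 0])) > 1:
        logger.warning("AICc trace not unimodal over the grid; "
                       "using the global trace minimum")
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]

    # golden-section in log-bandwidth within the bracketing interval
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = math.log(lo), math.log(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    while (b - a) > rel_tol:
        if aicc_of(float(math.exp(c))) <= aicc_of(float(math.exp(d))):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    best = min(cache, key=cache.get)
    trace = (pd.DataFrame(sorted(cache.items()), columns=["bandwidth", "aicc"])
             .reset_index(drop=True))
    return float(best), trace


# ---------------------------------------------------------------- Moran's I

@dataclass(frozen=True)
class MoranResult:
    i: float
    expected: float
    p_value: float
    permutations: int
    applicable: bool = True


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardized k-nearest-neighbour weight matrix (dense)."""
    coords = np.asarray(coords, float)
    n = len(coords)
    if k >= n:
        raise ConfigurationError("k must be smaller than the number of points")
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    w = np.zeros((n, n))
    for i in range(n):
        neighbours = [j for j in idx[i] if j != i][:k]
        w[i, neighbours] = 1.0 / len(neighbours)
    return w


def morans_i(values: np.ndarray, coords: np.ndarray, k: int = 8,
             permutations: int = 999, seed: int = 0) -> MoranResult:
    """Moran's I with k-NN row-standardized weights and a two-tailed
    permutation pseudo p-value. Expected value under no autocorrelation is
    -1/(n-1). Constant inputs yield a not-applicable result."""
    values = np.asarray(values, float)
    coords = np.asarray(coords, float)
    n = len(values)
    if n < 4:
        raise ConfigurationError("need at least 4 observations")
    z = values - values.mean()
    denom = float(z @ z)
    expected = -1.0 / (n - 1)
    if denom == 0.0:
        return MoranResult(float("nan"), expected, float("nan"),
                           permutations, applicable=False)
    w = knn_weights(coords, k=k)
    s0 = w.sum()

    def stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ (w @ zv)) / (zv @ zv))

    i_obs = stat(z)
    rng = np.random.default_rng(seed)
    sims = np.array([stat(rng.permutation(z)) for _ in range(permutations)])
    # directional pseudo p-value (permutation-test convention): tail on the
    # side of the observed statistic relative to the simulated mean
    if i_obs >= sims.mean():
        p = (1 + int((sims >= i_obs).sum())) / (permutations + 1)
    else:
        p = (1 + int((sims <= i_obs).sum())) / (permutations + 1)
    return MoranResult(i_obs, expected, p, permutations)


# ---------------------------------------------------------------- reporting

def gwr_report(fit: GwrFit, index=None) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-location table (coefficients, fitted, residuals, standardized
    residuals with over/under-prediction sign, local R^2) and a global
    summary dict."""
    cols = fit.columns or tuple(
        f"beta_{j}" for j in range(fit.coefficients.shape[1]))
    table = pd.DataFrame(fit.coefficients, columns=[f"coef_{c}" for c in cols])
    table["fitted"] = fit.fitted
    table["residual"] = fit.residuals
    table["std_residual"] = fit.std_residuals
    table["residual_sign"] = np.sign(fit.residuals).astype(int)
    table["local_r2"] = fit.local_r2
    if index is not None:
        table.index = pd.Index(index)
        table.index.name = "city_code"
    summary = fit.summary()
    if fit.moran is not None:
        summary.update({"moran_i": fit.moran.i,
                        "moran_expected": fit.moran.expected,
                        "moran_p": fit.moran.p_value})
    return table, summary
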