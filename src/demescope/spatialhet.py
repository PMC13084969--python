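"""Spatial interpolation of individual heterozygosity by ordinary kriging.

An empirical semivariogram of the observations is fit with an exponential
model gamma(h) = nugget + psill * (1 - exp(-h / range)); grid-node
predictions use ordinary kriging (weights constrained to sum to one through a
Lagrange multiplier) on the k nearest observations (default 36), with the
exponential covariance C(h) = psill * exp(-h / range) and the nugget on the
system diagonal.  The surface is reported both on the data scale and as
z-scores: predicted deviation from the global mean of the observations in
units of their standard deviation.

Distances are great-circle km on lon/lat; at deme scale (tens of km) no map
projection is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .structstats import haversine_km

__all__ = [
    "EmpiricalVariogram",
    "VariogramModel",
    "KrigedSurface",
    "empirical_semivariogram",
    "fit_exponential",
    "make_grid",
    "krige",
    "zscore_surface",
    "krige_heterozygosity",
]

log = logging.getLogger(__name__)


@dataclass
class EmpiricalVariogram:
    """Binned semivariance: gamma(bin) = sum (v_i - v_j)^2 / (2 N_bin)."""

    bin_centers: np.ndarray  # km
    gamma: np.ndarray  # NaN for empty bins
    pair_counts: np.ndarray


@dataclass
class VariogramModel:
    nugget: float
    psill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.psill < 0 or self.range_km <= 0:
            raise ValueError("need nugget >= 0, psill >= 0, range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def gamma(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.nugget + self.psill * (1.0 - np.exp(-h / self.range_km))

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """C(h) = psill * exp(-h/range); the nugget acts only at h = 0."""
        return self.psill * np.exp(-np.asarray(h, dtype=float) / self.range_km)


@dataclass
class KrigedSurface:
    """Gridded kriging output.

    ``x``/``y`` are grid-node lon/lat; ``prediction`` and ``variance`` have
    shape (n_y, n_x); ``zscore`` (same shape) is filled by
    :func:`zscore_surface`.
    """

    x: np.ndarray
    y: np.ndarray
    prediction: np.ndarray
    variance: np.ndarray
    zscore: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        df = pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "prediction": self.prediction.ravel(),
                "variance": self.variance.ravel(),
            }
        )
        if self.zscore is not None:
            df["z"] = self.zscore.ravel()
        return df


def empirical_semivariogram(
    lon: np.ndarray,
    lat: np.ndarray,
    values: np.ndarray,
    n_bins: int = 12,
    max_lag: float | None = None,
) -> EmpiricalVariogram:
    """Equal-width-bin empirical semivariogram over all point pairs.

    Empty bins are reported as NaN (absent), not zero.  At least two points
    are required; ten or more are recommended for a usable variogram.
    """
    lon, lat = np.asarray(lon, float), np.asarray(lat, float)
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need at least 2 points")
    if len(v) < 10:
        log.info("semivariogram from only %d points; >= 10 recommended", len(v))
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    iu, ju = np.triu_indices(len(v), k=1)
    h = d[iu, ju]
    sq = (v[iu] - v[ju]) ** 2
    if max_lag is None:
        max_lag = h.max()
    if max_lag > h.max():
        raise ValueError("max_lag exceeds the largest pairwise distance")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    inside = h <= max_lag
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = inside & (which == b)
        counts[b] = sel.sum()
        if counts[b]:
            gamma[b] = sq[sel].sum() / (2.0 * counts[b])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma, counts)


def fit_exponential(empirical: EmpiricalVariogram) -> VariogramModel:
    """Weighted least-squares exponential fit to an empirical semivariogram.

    Weights are the per-bin pair counts; parameters are bounded non-negative.
    Starting values: nugget 0, psill = max binned semivariance, range =
    one-third of the largest bin center.  A degenerate fit (psill ~ 0)
    returns a pure-nugget model with a warning.
    """
    ok = ~np.isnan(empirical.gamma)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-empty bins")
    h = empirical.bin_centers[ok]
    g = empirical.gamma[ok]
    w = np.sqrt(empirical.pair_counts[ok].astype(float))
    g_max = max(g.max(), 1e-12)
    x0 = np.array([0.0, g_max, max(h.max() / 3.0, 1e-6)])

    def resid(theta):
        nugget, psill, rng_ = theta
        model = nugget + psill * (1.0 - np.exp(-h / rng_))
        return w * (model - g)

    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
    )
    nugget, psill, rng_ = sol.x
    if psill < 1e-6 * g_max or rng_ < h[h > 0].min() / 100.0:
        warnings.warn("variogram fit degenerate (psill ~ 0); pure-nugget model")
        return VariogramModel(
            nugget=float(max(nugget, g.mean())), psill=0.0,
            range_km=float(max(rng_, 1e-6)),
        )
    return VariogramModel(float(nugget), float(psill), float(rng_))


def make_grid(
    lon: np.ndarray, lat: np.ndarray, n_x: int = 100, n_y: int = 100,
    pad: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Regular lon/lat grid over the padded bounding box of the samples."""
    lon, lat = np.asarray(lon, float), np.asarray(lat, float)
    dx = (lon.max() - lon.min()) or 1.0
    dy = (lat.max() - lat.min()) or 1.0
    gx = np.linspace(lon.min() - pad * dx, lon.max() + pad * dx, n_x)
    gy = np.linspace(lat.min() - pad * dy, lat.max() + pad * dy, n_y)
    return gx, gy


def _dedupe(
    lon: np.ndarray, lat: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average values at coincident coordinates (singular-system guard)."""
    df = pd.DataFrame({"lon": lon, "lat": lat, "v": values})
    agg = df.groupby(["lon", "lat"], sort=False, as_index=False)["v"].mean()
    if len(agg) < len(df):
        log.info("kriging: averaged %d duplicate point(s)", len(df) - len(agg))
    return (
        agg["lon"].to_numpy(),
        agg["lat"].to_numpy(),
        agg["v"].to_numpy(),
    )


def krige(
    lon: np.ndarray,
    lat: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    k_neighbors: int = 36,
) -> KrigedSurface:
    """Ordinary kriging on the k nearest observations per grid node.

    For each node the ordinary-kriging system
    ``[[C + nugget*I, 1], [1', 0]] [w; mu] = [c0; 1]`` is solved on the
    ``k_neighbors`` nearest observations (great-circle distance), giving
    prediction ``w . v`` and variance ``sill - w . c0 - mu``.  With a zero
    nugget the predictor interpolates the observations exactly.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    lon, lat, v = _dedupe(
        np.asarray(lon, float), np.asarray(lat, float), np.asarray(values, float)
    )
    n = len(v)
    k = min(k_neighbors, n)
    d_obs = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    cov_obs = model.covariance(d_obs)
    np.fill_diagonal(cov_obs, model.sill)

    nx, ny = len(grid_x), len(grid_y)
    pred = np.empty((ny, nx))
    var = np.empty((ny, nx))
    for iy, y0 in enumerate(grid_y):
        d_node = haversine_km(grid_x[None, :], y0, lon[:, None], lat[:, None])
        for ix in range(nx):
            dn = d_node[:, ix]
            nbr = np.argpartition(dn, k - 1)[:k] if k < n else np.arange(n)
            a = np.empty((k + 1, k + 1))
            a[:k, :k] = cov_obs[np.ix_(nbr, nbr)]
            a[k, :k] = 1.0
            a[:k, k] = 1.0
            a[k, k] = 0.0
            rhs = np.empty(k + 1)
            rhs[:k] = model.covariance(dn[nbr])
            rhs[k] = 1.0
            try:
                sol = np.linalg.solve(a, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(a, rhs, rcond=None)
            w, mu = sol[:k], sol[k]
            pred[iy, ix] = w @ v[nbr]
            var[iy, ix] = max(model.sill - w @ rhs[:k] - mu, 0.0)
    return KrigedSurface(x=np.asarray(grid_x), y=np.asarray(grid_y),
                         prediction=pred, variance=var)


def zscore_surface(surface: KrigedSurface, values: np.ndarray) -> KrigedSurface:
    """Express predictions as s.d. deviations from the observed global mean.

    z = (prediction - mean(values)) / sd(values), with sd the sample
    standard deviation (ddof=1) of the observations.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("observations have zero standard deviation")
    surface.zscore = (surface.prediction - v.mean()) / sd
    return surface


def krige_heterozygosity(
    lon: np.ndarray,
    lat: np.ndarray,
    h_o: np.ndarray,
    k_neighbors: int = 36,
    n_x: int = 100,
    n_y: int = 100,
    n_bins: int = 12,
) -> tuple[KrigedSurface, VariogramModel, EmpiricalVariogram]:
    """Variogram -> fit -> krige -> z-score in one call (the default map)."""
    emp = empirical_semivariogram(lon, lat, h_o, n_bins=n_bins)
    model = fit_exponential(emp)
    gx, gy = make_grid(lon, lat, n_x=n_x, n_y=n_y)
    surf = krige(lon, lat, h_o, model, gx, gy, k_neighbors=k_neighbors)
    return zscore_surface(surf, h_o), model, emp
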