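"""Kriged feather isoscapes over the non-breeding centroids.

One isotope value per centroid (the feather value of the bird whose
non-breeding centroid it is; centroids sharing a cell are averaged) is
interpolated by ordinary kriging with a spherical semivariogram fitted by
weighted least squares, and the surface is limited to a 4-degree buffer
around the centroids. Distances default to planar degrees, the convention of
grid-based GIS kriging on unprojected geographic data; a haversine-km mode is
available. A Mollweide (equal-area) transform is provided for rendering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares

from .space_use import haversine_km

__all__ = [
    "VariogramModel",
    "KrigedGrid",
    "empirical_variogram",
    "fit_spherical",
    "krige",
    "buffer_mask",
    "mollweide_forward",
    "mollweide_inverse",
    "write_ascii_grid",
    "mask_outline_geojson",
]

EARTH_RADIUS_M = 6371000.0


@dataclass
class VariogramModel:
    """Spherical semivariogram: nugget c0, partial sill c, range a."""

    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self):
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("variogram parameters must be nonnegative, range positive")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = np.clip(h / self.range_, 0.0, 1.0)
        gamma = self.nugget + self.partial_sill * (1.5 * r - 0.5 * r**3)
        return np.where(h == 0.0, 0.0, gamma)


def _pairwise(lons, lats, metric: str) -> np.ndarray:
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if metric == "degrees":
        return np.hypot(lons[:, None] - lons[None, :], lats[:, None] - lats[None, :])
    if metric == "km":
        return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    raise ValueError(f"unknown metric {metric!r}")


def empirical_variogram(
    lons,
    lats,
    values,
    n_lags: int = 12,
    max_lag: float | None = None,
    metric: str = "degrees",
) -> np.ndarray:
    """Binned semivariance table: columns (lag centre h, gamma(h), pair count).

    gamma(h) is the mean of half squared differences over point pairs whose
    separation falls in the bin. Empty bins are dropped.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 points")
    d = _pairwise(lons, lats, metric)
    iu = np.triu_indices(len(values), k=1)
    h = d[iu]
    if np.all(h == 0):
        raise ValueError("all points coincident")
    sq = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    if max_lag is None:
        max_lag = float(h.max())
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    rows = []
    for i in range(n_lags):
        in_bin = (h > edges[i]) & (h <= edges[i + 1]) if i else (h >= edges[i]) & (h <= edges[i + 1])
        if in_bin.sum() == 0:
            continue
        rows.append([0.5 * (edges[i] + edges[i + 1]), sq[in_bin].mean(), int(in_bin.sum())])
    return np.asarray(rows)


def fit_spherical(lag_table: np.ndarray) -> VariogramModel:
    """Weighted least-squares spherical fit (weights = pair counts).

    Falls back to (nugget 0, sill = mean semivariance, range = max lag / 2)
    with a warning when the fit fails or degenerates (e.g. a flat variogram
    leaves the range unidentifiable).
    """
    lag_table = np.asarray(lag_table, dtype=float)
    if len(lag_table) < 3:
        raise ValueError("need at least 3 nonempty lags")
    h, gamma, npairs = lag_table.T
    w = np.sqrt(npairs)

    def resid(theta):
        c0, c, a = theta
        return w * (VariogramModel(max(c0, 0), max(c, 0), max(a, 1e-9))(h) - gamma)

    sill0 = gamma[-3:].mean() if len(gamma) >= 3 else gamma.mean()
    x0 = [max(gamma[0] * 0.5, 1e-9), max(sill0 - gamma[0] * 0.5, 1e-9), h.max() / 2]
    fallback = VariogramModel(0.0, float(max(gamma.mean(), 1e-12)), float(h.max() / 2))
    try:
        sol = least_squares(
            resid, x0, bounds=([0, 0, 1e-9], [np.inf, np.inf, 10 * h.max()])
        )
    except Exception:
        warnings.warn("spherical variogram fit failed: using fallback parameters")
        return fallback
    c0, c, a = sol.x
    flat = np.ptp(gamma) < 1e-12 * max(1.0, abs(gamma[0]))
    if not sol.success or flat or a >= 9.99 * h.max():
        warnings.warn("spherical variogram fit degenerate: using fallback parameters")
        return fallback
    return VariogramModel(float(c0), float(c), float(a))


@dataclass
class KrigedGrid:
    """Ordinary-kriging surface on a regular lon/lat grid."""

    lons: np.ndarray  # cell centres, ascending
    lats: np.ndarray
    values: np.ndarray  # (nlat, nlon), NaN where masked
    variance: np.ndarray
    mask: np.ndarray  # True where predicted

    def mean_over(self, mask: np.ndarray) -> float:
        sel = mask & self.mask
        return float(np.nanmean(self.values[sel]))


def _dedup(lons, lats, values):
    pts = {}
    for lo, la, v in zip(lons, lats, values):
        pts.setdefault((round(lo, 9), round(la, 9)), []).append(v)
    if any(len(v) > 1 for v in pts.values()):
        warnings.warn("duplicate kriging points averaged")
    out = np.array([[k[0], k[1], float(np.mean(v))] for k, v in sorted(pts.items())])
    return out[:, 0], out[:, 1], out[:, 2]


def krige(
    lons,
    lats,
    values,
    variogram: VariogramModel,
    grid_lons: np.ndarray,
    grid_lats: np.ndarray,
    mask: np.ndarray | None = None,
    metric: str = "degrees",
) -> KrigedGrid:
    """Ordinary kriging of point values onto a grid.

    Solves the augmented system with a Lagrange multiplier per cell; weights
    sum to 1 (unbiasedness). Exact at data locations when the nugget is zero.
    ``mask`` restricts prediction to True cells.
    """
    lons, lats, values = _dedup(
        np.asarray(lons, float), np.asarray(lats, float), np.asarray(values, float)
    )
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 points to krige")
    gamma_pp = variogram(_pairwise(lons, lats, metric))
    a_mat = np.empty((n + 1, n + 1))
    a_mat[:n, :n] = gamma_pp
    a_mat[n, :] = 1.0
    a_mat[:, n] = 1.0
    a_mat[n, n] = 0.0
    lu = lu_factor(a_mat)

    glon, glat = np.meshgrid(grid_lons, grid_lats)
    if mask is None:
        mask = np.ones(glon.shape, dtype=bool)
    cl = glon[mask]
    cb = glat[mask]
    if metric == "degrees":
        d0 = np.hypot(cl[None, :] - lons[:, None], cb[None, :] - lats[:, None])
    else:
        d0 = haversine_km(lons[:, None], lats[:, None], cl[None, :], cb[None, :])
    b = np.empty((n + 1, len(cl)))
    b[:n] = variogram(d0)
    b[n] = 1.0
    sol = lu_solve(lu, b)
    w = sol[:n]
    mu = sol[n]
    pred = w.T @ values
    var = np.einsum("ij,ij->j", w, b[:n]) + mu
    val_grid = np.full(glon.shape, np.nan)
    var_grid = np.full(glon.shape, np.nan)
    val_grid[mask] = pred
    var_grid[mask] = np.maximum(var, 0.0)
    return KrigedGrid(
        lons=np.asarray(grid_lons, float),
        lats=np.asarray(grid_lats, float),
        values=val_grid,
        variance=var_grid,
        mask=mask.copy(),
    )


def buffer_mask(
    centroid_lons,
    centroid_lats,
    grid_lons: np.ndarray,
    grid_lats: np.ndarray,
    radius_deg: float = 4.0,
) -> np.ndarray:
    """True where a grid cell centre lies within ``radius_deg`` (planar
    degrees) of any centroid — the union of per-centroid buffers."""
    centroid_lons = np.atleast_1d(np.asarray(centroid_lons, float))
    centroid_lats = np.atleast_1d(np.asarray(centroid_lats, float))
    if centroid_lons.size == 0:
        raise ValueError("need at least one centroid")
    glon, glat = np.meshgrid(np.asarray(grid_lons, float), np.asarray(grid_lats, float))
    d = np.hypot(
        glon[..., None] - centroid_lons[None, None, :],
        glat[..., None] - centroid_lats[None, None, :],
    )
    return (d <= radius_deg).any(axis=-1)


def mollweide_forward(lon, lat, lon0: float = 0.0, radius: float = EARTH_RADIUS_M):
    """Equal-area Mollweide projection; returns (x, y) in metres.

    The auxiliary angle theta solves 2 theta + sin 2 theta = pi sin(lat) by
    Newton iteration.
    """
    lon = np.radians(np.asarray(lon, dtype=float) - lon0)
    phi = np.radians(np.asarray(lat, dtype=float))
    theta = phi.copy()
    polar = np.abs(np.abs(phi) - np.pi / 2) < 1e-12
    for _ in range(50):
        f = 2 * theta + np.sin(2 * theta) - np.pi * np.sin(phi)
        df = 2 + 2 * np.cos(2 * theta)
        step = np.where(np.abs(df) > 1e-12, f / df, 0.0)
        theta = theta - step
        if np.max(np.abs(step)) < 1e-14:
            break
    theta = np.where(polar, np.sign(phi) * np.pi / 2, theta)
    x = radius * 2 * np.sqrt(2) / np.pi * lon * np.cos(theta)
    y = radius * np.sqrt(2) * np.sin(theta)
    return x, y


def mollweide_inverse(x, y, lon0: float = 0.0, radius: float = EARTH_RADIUS_M):
    """Inverse Mollweide; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    theta = np.arcsin(np.clip(y / (radius * np.sqrt(2)), -1.0, 1.0))
    phi = np.arcsin(np.clip((2 * theta + np.sin(2 * theta)) / np.pi, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.pi * x / (2 * radius * np.sqrt(2) * np.cos(theta))
    lam = np.where(np.abs(np.cos(theta)) < 1e-12, 0.0, lam)
    return np.degrees(lam) + lon0, np.degrees(phi)


def write_ascii_grid(grid: KrigedGrid, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII raster of the kriged values (row order: north to south)."""
    cell = float(grid.lons[1] - grid.lons[0])
    vals = np.where(np.isfinite(grid.values), grid.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {len(grid.lons)}\n")
        fh.write(f"nrows {len(grid.lats)}\n")
        fh.write(f"xllcorner {grid.lons[0] - cell / 2:.6f}\n")
        fh.write(f"yllcorner {grid.lats[0] - cell / 2:.6f}\n")
        fh.write(f"cellsize {cell:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in vals[::-1]:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


def mask_outline_geojson(
    mask: np.ndarray, grid_lons: np.ndarray, grid_lats: np.ndarray, path=None
) -> dict:
    """GeoJSON outline of the prediction mask (union of unmasked cell boxes)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    cell = float(grid_lons[1] - grid_lons[0])
    boxes = [
        box(
            grid_lons[j] - cell / 2,
            grid_lats[i] - cell / 2,
            grid_lons[j] + cell / 2,
            grid_lats[i] + cell / 2,
        )
        for i, j in zip(*np.nonzero(mask))
    ]
    geom = unary_union(boxes)
    feature = {
        "type": "Feature",
        "geometry": mapping(geom),
        "properties": {"role": "kriging_mask"},
    }
    doc = {"type": "FeatureCollection", "features": [feature]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh)
    return doc
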