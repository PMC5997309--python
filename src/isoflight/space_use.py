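"""Non-breeding space use: utilization distributions, centroids, clustering.

The chain reproduced here: per bird-year, a bivariate Gaussian kernel density
estimate of the non-breeding positions; the 5% isopleth (highest-density core)
reduced to its centroid; a great-circle distance matrix over all centroids;
partitioning around medoids (PAM) with the number of clusters chosen by the
maximal overall average silhouette width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UtilizationGrid",
    "Clustering",
    "haversine_km",
    "kde_ud",
    "isopleth_centroid",
    "isopleth_polygons_geojson",
    "distance_matrix",
    "pam",
    "silhouette_widths",
    "select_k",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (haversine, spherical Earth R=6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class UtilizationGrid:
    """A gridded utilization distribution in geographic coordinates.

    ``density`` holds probability mass per cell (sums to 1), indexed
    [row=lat, col=lon]; ``lons``/``lats`` are cell-centre coordinates.
    """

    lons: np.ndarray
    lats: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def cell_size(self) -> float:
        return float(self.lons[1] - self.lons[0]) if len(self.lons) > 1 else np.nan

    def total_mass(self) -> float:
        return float(self.density.sum())


def kde_ud(
    lons,
    lats,
    bandwidth: float | str = "href",
    cell_deg: float = 0.25,
    margin_bw: float = 3.5,
) -> UtilizationGrid:
    """Bivariate Gaussian KDE of positions on a lon/lat grid.

    ``bandwidth="href"`` uses the ad hoc reference bandwidth
    sqrt(0.5 (var_lon + var_lat)) n^(-1/6) applied isotropically to both axes,
    the convention of the home-range literature for geographic coordinates.
    The grid extends ``margin_bw`` bandwidths beyond the data and the cell
    masses are normalized to total 1.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = lons.size
    if n < 5:
        raise ValueError("need at least 5 positions for a utilization distribution")
    if bandwidth == "href":
        h = float(np.sqrt(0.5 * (lons.var(ddof=1) + lats.var(ddof=1))) * n ** (-1 / 6))
    else:
        h = float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pad = margin_bw * h
    gx = np.arange(lons.min() - pad, lons.max() + pad + cell_deg, cell_deg)
    gy = np.arange(lats.min() - pad, lats.max() + pad + cell_deg, cell_deg)
    dx = (gx[None, :] - lons[:, None]) / h
    dy = (gy[None, :] - lats[:, None]) / h
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    dens = ky.T @ kx  # (nlat, nlon) sum over points of separable kernels
    dens /= dens.sum()
    return UtilizationGrid(lons=gx, lats=gy, density=dens, bandwidth=h)


def _isopleth_cells(ud: UtilizationGrid, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of the smallest cell set holding ``level``% of total mass."""
    if not 0.0 < level < 100.0:
        raise ValueError("isopleth level must lie in (0, 100)")
    dens = ud.density
    if dens.sum() <= 0:
        raise ValueError("empty utilization distribution")
    flat = dens.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, level / 100.0 * flat.sum()) + 1)
    return np.unravel_index(order[:k], dens.shape)


def isopleth_centroid(ud: UtilizationGrid, level: float = 5.0) -> tuple[float, float]:
    """Density-weighted centroid of the ``level``% highest-density region.

    The region is the smallest set of cells holding ``level``% of total mass
    (cells taken in decreasing density order), i.e. the core-use area.
    """
    rows, cols = _isopleth_cells(ud, level)
    w = ud.density[rows, cols]
    lon = float(np.average(ud.lons[cols], weights=w))
    lat = float(np.average(ud.lats[rows], weights=w))
    return lon, lat


def distance_matrix(lons, lats) -> np.ndarray:
    """Symmetric great-circle distance matrix (km) among centroids."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 2:
        raise ValueError("need at least 2 centroids")
    if np.any(np.abs(lats) > 90) or np.any(np.abs(lons) > 360):
        raise ValueError("invalid coordinates")
    d = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


@dataclass
class Clustering:
    """A PAM solution: medoid indices, labels, cost and silhouette."""

    k: int
    medoids: np.ndarray
    labels: np.ndarray
    cost: float
    avg_silhouette: float = np.nan
    silhouette_profile: dict[int, float] = field(default_factory=dict)


def _assign(dist: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = dist[:, medoids]
    labels = np.argmin(sub, axis=1)
    return labels, float(sub[np.arange(len(dist)), labels].sum())


def pam(dist: np.ndarray, k: int, max_iter: int = 100) -> Clustering:
    """Partitioning around medoids: greedy BUILD then best-improvement SWAP.

    Deterministic: ties break to the lowest index. The returned configuration
    is a local minimum of total dissimilarity to medoids (no single
    medoid/non-medoid swap improves it).
    """
    dist = np.asarray(dist, dtype=float)
    n = len(dist)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    if k == n:
        medoids = np.arange(n)
        return Clustering(k=k, medoids=medoids, labels=np.arange(n), cost=0.0)

    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    dmin = dist[:, medoids[0]].copy()
    for _ in range(k - 1):
        gains = np.maximum(dmin[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        dmin = np.minimum(dmin, dist[:, best])
    medoids = np.array(sorted(medoids))

    _, cost = _assign(dist, medoids)
    for _ in range(max_iter):
        sub = dist[:, medoids]
        nearest = sub.argmin(axis=1)
        if k > 1:
            part = np.partition(sub, 1, axis=1)
            d1, d2 = part[:, 0], part[:, 1]
        else:
            d1, d2 = sub[:, 0], np.full(n, np.inf)
        best_delta = 0.0
        best_swap = None
        for mi in range(k):
            # removal cost baseline: points attached to medoid mi fall back to d2
            base = np.where(nearest == mi, d2, d1)
            # candidate new costs for every possible replacement h
            newcost = np.minimum(base[:, None], dist).sum(axis=0)
            newcost[medoids] = np.inf
            h = int(np.argmin(newcost))
            delta = newcost[h] - cost
            if delta < best_delta - 1e-12:
                best_delta = delta
                best_swap = (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids = medoids.copy()
        medoids[mi] = h
        medoids = np.sort(medoids)
        _, cost = _assign(dist, medoids)
    labels, cost = _assign(dist, medoids)
    return Clustering(k=k, medoids=medoids, labels=labels, cost=cost)


def silhouette_widths(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette s(i) = (b-a)/max(a,b) from a distance matrix.

    Points in singleton clusters get silhouette 0.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    s = np.zeros(n)
    means = np.empty((n, len(uniq)))
    sizes = np.empty(len(uniq))
    for j, c in enumerate(uniq):
        mask = labels == c
        sizes[j] = mask.sum()
        means[:, j] = dist[:, mask].sum(axis=1) / np.maximum(mask.sum(), 1)
    for i in range(n):
        j_own = int(np.nonzero(uniq == labels[i])[0][0])
        n_own = sizes[j_own]
        if n_own <= 1:
            s[i] = 0.0
            continue
        a = means[i, j_own] * n_own / (n_own - 1)  # exclude self
        b = np.min(np.delete(means[i], j_own))
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def select_k(dist: np.ndarray, k_range=range(2, 11)) -> Clustering:
    """PAM at each k; return the clustering maximizing mean silhouette width."""
    dist = np.asarray(dist, dtype=float)
    n = len(dist)
    if n <= 3:
        raise ValueError("need more than 3 points to select k")
    ks = [k for k in k_range if 2 <= k < n]
    if not ks:
        raise ValueError("empty usable k range")
    profile: dict[int, float] = {}
    best: Clustering | None = None
    for k in ks:
        c = pam(dist, k)
        c.avg_silhouette = float(silhouette_widths(dist, c.labels).mean())
        profile[k] = c.avg_silhouette
        if best is None or c.avg_silhouette > best.avg_silhouette:
            best = c
    assert best is not None
    best.silhouette_profile = profile
    return best


def centroid_table(
    positions: pd.DataFrame,
    bandwidth: float | str = "href",
    cell_deg: float = 0.25,
    level: float = 5.0,
) -> pd.DataFrame:
    """Per-bird 5% isopleth centroids from a non-breeding positions table.

    ``positions`` needs columns bird_id, lon, lat; rows already restricted to
    the (last) non-breeding period and to unflagged fixes.
    """
    rows = []
    for bird, grp in positions.groupby("bird_id", sort=True):
        if len(grp) < 5:
            warnings.warn(f"{bird}: fewer than 5 positions, skipped")
            continue
        ud = kde_ud(grp["lon"].to_numpy(), grp["lat"].to_numpy(), bandwidth, cell_deg)
        lon, lat = isopleth_centroid(ud, level)
        rows.append({"bird_id": bird, "lon": lon, "lat": lat})
    return pd.DataFrame(rows)


def isopleth_polygons_geojson(
    positions: pd.DataFrame,
    path=None,
    bandwidth: float | str = "href",
    cell_deg: float = 0.25,
    level: float = 5.0,
) -> dict:
    """Per-bird ``level``% isopleth regions as a GeoJSON FeatureCollection.

    Each feature is the union of the core-use grid cells of one bird
    (properties: bird_id, level).
    """
    import json

    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    features = []
    for bird, grp in positions.groupby("bird_id", sort=True):
        if len(grp) < 5:
            continue
        ud = kde_ud(grp["lon"].to_numpy(), grp["lat"].to_numpy(), bandwidth, cell_deg)
        rows, cols = _isopleth_cells(ud, level)
        half = cell_deg / 2
        cells = [
            box(ud.lons[j] - half, ud.lats[i] - half, ud.lons[j] + half, ud.lats[i] + half)
            for i, j in zip(rows, cols)
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(unary_union(cells)),
                "properties": {"bird_id": str(bird), "level": level},
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh)
    return doc
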