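"""Study-scale experiments used by the validation suite and the results script.

Each function re-runs a slice of the pipeline at the study design (86
bird-years, ~65 Central / 21 South Atlantic, published isotope class
parameters) and returns the summary quantity of interest. They are pure
functions of their seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geolocation as geo
from . import isoscape as isc
from . import isotopes as iso
from . import solar
from . import space_use as su
from . import synthetic as syn

__all__ = [
    "cluster_count_replicates",
    "area_assignment_accuracy",
    "geolocation_roundtrip_errors",
    "isoscape_gradient_experiment",
]


def cluster_count_replicates(
    n_replicates: int = 100,
    n_per_area: tuple[int, int] = (65, 21),
    noise_sd_deg: float = 2.0,
    base_seed: int = 0,
) -> list[int]:
    """Silhouette-selected k for replicated 86-centroid two-area designs."""
    ks = []
    for r in range(n_replicates):
        cen = syn.sample_area_centroids(
            n_per_area=n_per_area, noise_sd_deg=noise_sd_deg,
            rng_seed=base_seed + r,
        )
        d = su.distance_matrix(cen["lon"], cen["lat"])
        ks.append(su.select_k(d).k)
    return ks


def _area_feather_table(
    feather: str, n_central: int, n_south: int, rng_seed: int
) -> pd.DataFrame:
    """Per-bird feather draws at the published area class parameters."""
    lut = {(p.feather, p.label): p for p in syn.make_default_isotope_params()}
    rng = np.random.default_rng(rng_seed)
    rows = []
    for area, n in (
        (syn.CENTRAL_ATLANTIC, n_central),
        (syn.SOUTH_ATLANTIC, n_south),
    ):
        p = lut[(feather, area)]
        draws = rng.multivariate_normal(p.mean, p.cov, size=n)
        for i, (d15n, d13c) in enumerate(draws):
            rows.append(
                {
                    "bird_id": f"{area}_{i:03d}",
                    "area": area,
                    "feather": feather,
                    "d15N": d15n,
                    "d13C": d13c,
                }
            )
    return pd.DataFrame(rows)


def area_assignment_accuracy(
    feather: str = "S8",
    n_splits: int = 100,
    n_central: int = 54,
    n_south: int = 30,
    base_seed: int = 0,
) -> np.ndarray:
    """Test-set correct-classification totals (%) over seeded 70/30 splits.

    Each replicate draws a fresh cohort at the published class parameters,
    splits it 70/30, fits the LDA on the training set only, and scores the
    held-out records.
    """
    out = np.empty(n_splits)
    for r in range(n_splits):
        df = _area_feather_table(feather, n_central, n_south, rng_seed=base_seed + 10_000 + r)
        train, test = iso.split_train_test(df, rng_seed=base_seed + 20_000 + r)
        model = iso.fit_lda(train, "area")
        out[r] = iso.classification_rates(model, train, test).total_test
    return out


def geolocation_roundtrip_errors(
    n_birds: int = 5,
    noise_sd_min: float = 2.0,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Per-fix great-circle position errors for noisy and noise-free twilights.

    Returns a frame with columns noise ("none"/"noisy"), error_km, lat_err_deg,
    lon_err_deg, restricted to unflagged (non-equinox) fixes.
    """
    tracks = syn.simulate_tracks(n_birds=n_birds, rng_seed=base_seed)
    frames = []
    for label, sd in (("none", 0.0), ("noisy", noise_sd_min)):
        for i, tr in enumerate(tracks):
            tw = syn.simulate_twilights(tr, noise_sd_min=sd, rng_seed=base_seed + 100 + i)
            pos = geo.filter_transitions(geo.positions_from_twilights(tw), tw)
            truth = tr.positions_frame()
            truth["date"] = pd.to_datetime(truth["date"])
            m = pos.merge(truth, on="date", suffixes=("_est", "_true"))
            clean = m[m["flags"] == ""]
            err = su.haversine_km(
                clean["lon_est"], clean["lat_est"], clean["lon_true"], clean["lat_true"]
            )
            frames.append(
                pd.DataFrame(
                    {
                        "noise": label,
                        "error_km": err,
                        "lon_err_deg": (clean["lon_est"] - clean["lon_true"]).abs(),
                        "lat_err_deg": (clean["lat_est"] - clean["lat_true"]).abs(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def isoscape_gradient_experiment(
    seed: int,
    n_per_area: tuple[int, int] = (65, 21),
    noise_sd_deg: float = 2.0,
    grid_cell_deg: float = 1.0,
    buffer_deg: float = 4.0,
    feathers: tuple[str, ...] = ("S8", "R6"),
) -> dict[str, float]:
    """One full centroid->cluster->feathers->kriging run; masked-region means.

    Clusters the simulated centroids (silhouette k-selection), names the
    lower-latitude cluster the South Atlantic, draws each bird's feather
    values from its true area class, kriges each isotope surface under the
    4-degree buffer, and returns mean surface values over the cluster-derived
    Central and South masks, keyed "<feather>_<isotope>_<area>".
    """
    cen = syn.sample_area_centroids(
        n_per_area=n_per_area, noise_sd_deg=noise_sd_deg, rng_seed=seed
    )
    d = su.distance_matrix(cen["lon"], cen["lat"])
    sol = su.select_k(d)
    cen = cen.copy()
    cen["cluster"] = sol.labels
    south_cluster = cen.groupby("cluster")["lat"].mean().idxmin()
    cen["assigned"] = np.where(
        cen["cluster"] == south_cluster, syn.SOUTH_ATLANTIC, syn.CENTRAL_ATLANTIC
    )
    gl = np.arange(cen["lon"].min() - 5, cen["lon"].max() + 5 + grid_cell_deg, grid_cell_deg)
    gb = np.arange(cen["lat"].min() - 5, cen["lat"].max() + 5 + grid_cell_deg, grid_cell_deg)
    masks = {
        area: isc.buffer_mask(
            cen.loc[cen["assigned"] == area, "lon"],
            cen.loc[cen["assigned"] == area, "lat"],
            gl, gb, buffer_deg,
        )
        for area in (syn.CENTRAL_ATLANTIC, syn.SOUTH_ATLANTIC)
    }
    full_mask = masks[syn.CENTRAL_ATLANTIC] | masks[syn.SOUTH_ATLANTIC]
    lut = {(p.feather, p.label): p for p in syn.make_default_isotope_params()}
    rng = np.random.default_rng(seed + 500_000)
    out: dict[str, float] = {"k": float(sol.k)}
    for feather in feathers:
        draws = np.array(
            [
                rng.multivariate_normal(lut[(feather, a)].mean, lut[(feather, a)].cov)
                for a in cen["area"]
            ]
        )
        for iso_col, name in ((0, "d15N"), (1, "d13C")):
            z = draws[:, iso_col]
            table = isc.empirical_variogram(cen["lon"], cen["lat"], z)
            vg = isc.fit_spherical(table)
            kg = isc.krige(cen["lon"], cen["lat"], z, vg, gl, gb, full_mask)
            for area, m in masks.items():
                out[f"{feather}_{name}_{area}"] = kg.mean_over(m)
    return out
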