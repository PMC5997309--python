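"""Config-driven orchestration: simulate -> geolocate -> cluster -> assign -> isoscape.

A run is a pure function of (RunConfig, seeds): every stage writes CSV/JSON
artifacts into the run directory and the manifest records SHA-256 digests of
all outputs, so reruns with identical configuration reproduce identical
digests. Stage defaults equal the study settings (light threshold 20, minimum
dark 4 h, equinox window 20 d, 95th-percentile speed filter, 5% isopleth,
70/30 split, 4-degree buffer); any of them can be overridden in the TOML
config but none changes silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geolocation as geo
from . import isoscape as isc
from . import isotopes as iso
from . import space_use as su
from . import synthetic as syn

log = logging.getLogger("isoflight")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_inputs"]

VALID_FEATHERS = set(syn.CORPSE_FEATHER_SEQUENCE) | {"R6"}


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's stated settings."""

    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "geolocate", "cluster", "assign", "isoscape")
    # simulate
    n_birds: int = 86
    area_mix: float = 21 / 86
    twilight_noise_sd_min: float = 2.0
    sun_elevation: float = -3.0
    simulate_immersion: bool = True
    # geolocate
    light_threshold: float = 20.0
    min_dark_hours: float = 4.0
    equinox_window_days: int = 20
    speed_percentile: float = 95.0
    colony_radius_km: float = 200.0
    # cluster
    isopleth_level: float = 5.0
    kde_cell_deg: float = 0.25
    k_min: int = 2
    k_max: int = 10
    # assign
    train_frac: float = 0.70
    assign_feathers: tuple[str, ...] = ("S8", "R6")
    # isoscape
    buffer_deg: float = 4.0
    grid_cell_deg: float = 1.0
    variogram_lags: int = 12

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for section in ("run", "simulate", "geolocate", "cluster", "assign", "isoscape"):
            flat.update(raw.get(section, {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "assign_feathers"):
            if key in flat:
                flat[key] = tuple(flat[key])
        return cls(**flat)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["assign_feathers"] = list(d["assign_feathers"])
        return d


@dataclass
class RunManifest:
    config: dict
    stages: dict[str, str] = field(default_factory=dict)  # stage -> status
    digests: dict[str, str] = field(default_factory=dict)  # file -> sha256
    wall_time_s: float = 0.0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False, float_format="%.6f")
    manifest.digests[path.name] = _sha256(path)


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute the enabled stages in order, writing artifacts and a manifest.

    Stages depend on their predecessors' files; running a later stage without
    them raises an error naming the stage that must run first.
    """
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    colonies = syn.make_default_colonies()
    areas = syn.make_default_areas()
    colony_by_name = {c.name: c for c in colonies}

    def require(fname: str, producer: str) -> Path:
        p = outdir / fname
        if not p.exists():
            raise FileNotFoundError(
                f"missing {fname}: run the {producer!r} stage first"
            )
        return p

    if "simulate" in config.stages:
        tracks = syn.simulate_tracks(
            colonies, areas, n_birds=config.n_birds, area_mix=config.area_mix,
            rng_seed=config.seed,
        )
        truth = pd.DataFrame(
            {
                "bird_id": [t.bird_id for t in tracks],
                "colony": [t.colony.name for t in tracks],
                "area": [t.area.name for t in tracks],
                "departure": [t.departure for t in tracks],
                "arrival": [t.arrival for t in tracks],
            }
        )
        _write_csv(truth, outdir / "truth.csv", manifest)
        tw = pd.concat(
            [
                syn.simulate_twilights(
                    t, config.sun_elevation, config.twilight_noise_sd_min,
                    rng_seed=config.seed + 1000 + i,
                )
                for i, t in enumerate(tracks)
            ],
            ignore_index=True,
        )
        _write_csv(tw, outdir / "twilights.csv", manifest)
        feathers = syn.simulate_feathers(tracks, rng_seed=config.seed + 1)
        _write_csv(feathers, outdir / "feathers.csv", manifest)
        if config.simulate_immersion:
            imm = pd.concat(
                [
                    syn.simulate_immersion(t, rng_seed=config.seed + 2000 + i)
                    for i, t in enumerate(tracks)
                ],
                ignore_index=True,
            )
            _write_csv(imm, outdir / "immersion.csv", manifest)
        manifest.stages["simulate"] = "completed"
        log.info("simulate: %d tracks, %d twilight rows", len(tracks), len(tw))

    if "geolocate" in config.stages:
        tw = pd.read_csv(
            require("twilights.csv", "simulate"),
            parse_dates=["date", "dawn_utc", "dusk_utc"],
        )
        pos = geo.positions_from_twilights(tw, config.sun_elevation)
        per_bird = []
        for bird, bird_tw in tw.groupby("bird_id"):
            bp = pos[pos["bird_id"] == bird].reset_index(drop=True)
            per_bird.append(
                geo.filter_transitions(
                    bp, bird_tw, config.min_dark_hours, config.equinox_window_days
                )
            )
        thr = geo.cohort_speed_threshold(per_bird, config.speed_percentile)
        log.info("geolocate: speed threshold %.1f km/day", thr)
        filtered = [geo.speed_filter(b, thr) for b in per_bird]
        allpos = pd.concat(filtered, ignore_index=True)
        _write_csv(allpos, outdir / "positions.csv", manifest)
        truth = pd.read_csv(require("truth.csv", "simulate"))
        imm_path = outdir / "immersion.csv"
        immersion = pd.read_csv(imm_path) if imm_path.exists() else None
        phen_rows = []
        for bird, bp in allpos.groupby("bird_id"):
            colony = colony_by_name[truth.set_index("bird_id").loc[bird, "colony"]]
            bird_imm = (
                immersion[immersion["bird_id"] == bird] if immersion is not None else None
            )
            ph = geo.nonbreeding_window(
                bp, colony.longitude, colony.latitude, immersion=bird_imm,
                radius_km=config.colony_radius_km,
            )
            phen_rows.append(dataclasses.asdict(ph))
        _write_csv(pd.DataFrame(phen_rows), outdir / "phenology.csv", manifest)
        manifest.stages["geolocate"] = "completed"

    if "cluster" in config.stages:
        allpos = pd.read_csv(require("positions.csv", "geolocate"), parse_dates=["date"])
        phen = pd.read_csv(require("phenology.csv", "geolocate"), parse_dates=["departure", "arrival"])
        usable = allpos[geo._usable(allpos)]
        merged = usable.merge(phen[["bird_id", "departure", "arrival"]], on="bird_id")
        nb = merged[
            (merged["date"] > merged["departure"] + pd.Timedelta(days=10))
            & (merged["date"] < merged["arrival"] - pd.Timedelta(days=10))
        ]
        cents = su.centroid_table(nb, cell_deg=config.kde_cell_deg, level=config.isopleth_level)
        su.isopleth_polygons_geojson(
            nb, outdir / "isopleths.geojson",
            cell_deg=config.kde_cell_deg, level=config.isopleth_level,
        )
        manifest.digests["isopleths.geojson"] = _sha256(outdir / "isopleths.geojson")
        dmat = su.distance_matrix(cents["lon"], cents["lat"])
        sel = su.select_k(dmat, range(config.k_min, config.k_max + 1))
        cents["cluster"] = sel.labels
        # name clusters by mean latitude: the southern one is the South Atlantic
        mean_lat = cents.groupby("cluster")["lat"].mean()
        south_label = mean_lat.idxmin()
        cents["area"] = np.where(
            cents["cluster"] == south_label, syn.SOUTH_ATLANTIC, syn.CENTRAL_ATLANTIC
        )
        _write_csv(cents, outdir / "centroids.csv", manifest)
        report = {
            "k": int(sel.k),
            "avg_silhouette": float(sel.avg_silhouette),
            "silhouette_profile": {str(k): v for k, v in sel.silhouette_profile.items()},
            "medoids": sel.medoids.tolist(),
        }
        with open(outdir / "cluster_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        manifest.digests["cluster_report.json"] = _sha256(outdir / "cluster_report.json")
        manifest.stages["cluster"] = "completed"
        log.info("cluster: k=%d, silhouette=%.3f", sel.k, sel.avg_silhouette)

    if "assign" in config.stages:
        feathers = pd.read_csv(require("feathers.csv", "simulate"))
        cents = pd.read_csv(require("centroids.csv", "cluster"))
        labelled = feathers.drop(columns=["area"]).merge(
            cents[["bird_id", "area"]], on="bird_id"
        )
        rows = []
        models = {}
        for feather in config.assign_feathers:
            sub = labelled[labelled["feather"] == feather].reset_index(drop=True)
            train, test = iso.split_train_test(
                sub, config.train_frac, rng_seed=config.seed + 5
            )
            model = iso.fit_lda(train, "area")
            models[feather] = model
            summary = iso.classification_rates(model, train, test)
            f = summary.to_frame()
            f.insert(0, "feather", feather)
            rows.append(f)
        confusion = pd.concat(rows, ignore_index=True)
        _write_csv(confusion, outdir / "confusion.csv", manifest)
        with open(outdir / "lda_models.json", "w") as fh:
            fh.write(
                json.dumps(
                    {f: json.loads(m.to_json()) for f, m in models.items()}, indent=2
                )
            )
        manifest.digests["lda_models.json"] = _sha256(outdir / "lda_models.json")
        manifest.stages["assign"] = "completed"

    if "isoscape" in config.stages:
        feathers = pd.read_csv(require("feathers.csv", "simulate"))
        cents = pd.read_csv(require("centroids.csv", "cluster"))
        cell = config.grid_cell_deg
        gl = np.arange(
            np.floor(cents["lon"].min()) - config.buffer_deg - 1,
            np.ceil(cents["lon"].max()) + config.buffer_deg + 1 + cell,
            cell,
        )
        gb = np.arange(
            np.floor(cents["lat"].min()) - config.buffer_deg - 1,
            np.ceil(cents["lat"].max()) + config.buffer_deg + 1 + cell,
            cell,
        )
        mask = isc.buffer_mask(cents["lon"], cents["lat"], gl, gb, config.buffer_deg)
        isc.mask_outline_geojson(mask, gl, gb, outdir / "mask.geojson")
        manifest.digests["mask.geojson"] = _sha256(outdir / "mask.geojson")
        for feather in config.assign_feathers:
            sub = feathers[feathers["feather"] == feather].merge(
                cents[["bird_id", "lon", "lat"]], on="bird_id"
            )
            for iso_col in ("d15N", "d13C"):
                table = isc.empirical_variogram(
                    sub["lon"], sub["lat"], sub[iso_col], config.variogram_lags
                )
                vg = isc.fit_spherical(table)
                kg = isc.krige(
                    sub["lon"], sub["lat"], sub[iso_col], vg, gl, gb, mask
                )
                out = outdir / f"isoscape_{feather}_{iso_col}.asc"
                isc.write_ascii_grid(kg, out)
                manifest.digests[out.name] = _sha256(out)
                log.info(
                    "isoscape %s %s: nugget=%.3f sill=%.3f range=%.2f",
                    feather, iso_col, vg.nugget, vg.partial_sill, vg.range_,
                )
        manifest.stages["isoscape"] = "completed"

    manifest.wall_time_s = time.time() - t0
    manifest.write(outdir / "manifest.json")
    return manifest


_SCHEMAS: dict[str, dict] = {
    "feathers": {
        "required": ["bird_id", "colony", "feather", "d15N", "d13C"],
        "checks": [
            (
                "feather code",
                lambda df: ~df["feather"].isin(sorted(VALID_FEATHERS)),
                "invalid feather code",
            ),
            (
                "d13C sign",
                lambda df: df["d13C"] > 0,
                "positive d13C: sign likely flipped",
            ),
            (
                "d15N range",
                lambda df: (df["d15N"] < 0) | (df["d15N"] > 30),
                "d15N outside plausible range",
            ),
        ],
    },
    "positions": {
        "required": ["bird_id", "timestamp_utc", "kind", "lon", "lat"],
        "checks": [
            ("latitude range", lambda df: df["lat"].abs() > 90, "latitude out of range"),
            ("longitude range", lambda df: df["lon"].abs() > 180, "longitude out of range"),
        ],
    },
    "twilights": {
        "required": ["bird_id", "date", "dawn_utc", "dusk_utc"],
        "checks": [],
    },
    "immersion": {
        "required": ["bird_id", "timestamp_utc", "wet_count"],
        "checks": [
            (
                "wet range",
                lambda df: (df["wet_count"] < 0) | (df["wet_count"] > 200),
                "wet_count outside 0..200",
            )
        ],
    },
    "centroids": {
        "required": ["bird_id", "lon", "lat"],
        "checks": [
            ("latitude range", lambda df: df["lat"].abs() > 90, "latitude out of range"),
        ],
    },
}


def validate_inputs(files: dict[str, "str | Path"]) -> list[dict]:
    """Schema- and range-check input CSVs; returns a machine-readable report.

    ``files`` maps a schema kind (feathers, positions, twilights, immersion,
    centroids) to a CSV path. Each violation is one dict; a clean input set
    yields an empty list.
    """
    report: list[dict] = []
    for kind, path in files.items():
        schema = _SCHEMAS.get(kind)
        if schema is None:
            report.append({"file": str(path), "kind": kind, "error": "unknown schema kind"})
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            report.append({"file": str(path), "kind": kind, "error": f"unreadable: {exc}"})
            continue
        missing = [c for c in schema["required"] if c not in df.columns]
        if missing:
            report.append(
                {"file": str(path), "kind": kind, "error": f"missing columns: {missing}"}
            )
            continue
        for name, predicate, message in schema["checks"]:
            bad = predicate(df)
            if bad.any():
                report.append(
                    {
                        "file": str(path),
                        "kind": kind,
                        "check": name,
                        "error": message,
                        "rows": df.index[bad][:20].tolist(),
                        "n_rows": int(bad.sum()),
                    }
                )
    return report
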