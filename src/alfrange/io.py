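"""Readers/writers, line rasterization, configuration, pipeline driver.

Interchange formats are all plain text and diff-able: ESRI ASCII grid
for rasters, GeoJSON for line networks and isopleths, CSV for tracks
and tabular artifacts, JSON for the run report, YAML for configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import LineString, box, mapping, shape

from . import folds as folds_mod
from . import locoh as locoh_mod
from . import od_metrics, selection as selection_mod
from .grids import GridSpec
from .models import build_dataset, fit_model, model_spec, predict_response_curve
from .synthetic import (
    ALF_TYPES,
    MovementParams,
    Track,
    gen_alf_lines,
    gen_landscape,
    simulate_track,
)

# ---------------------------------------------------------------------------
# rasters: ESRI ASCII grid
# ---------------------------------------------------------------------------
def write_ascii_raster(path, values: np.ndarray, grid: GridSpec) -> None:
    """ESRI ASCII grid (.asc); rows written north to south."""
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0!r}\n"
        f"cellsize {grid.cell!r}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values[::-1], fmt="%.8g")


def read_ascii_raster(path) -> tuple[np.ndarray, GridSpec]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    grid = GridSpec(
        x0=hdr["xllcorner"],
        y0=hdr["yllcorner"],
        cell=hdr["cellsize"],
        nrows=int(hdr["nrows"]),
        ncols=int(hdr["ncols"]),
    )
    return np.atleast_2d(values)[::-1].copy(), grid


# ---------------------------------------------------------------------------
# vector: GeoJSON
# ---------------------------------------------------------------------------
def write_lines_geojson(path, networks: dict[str, list[LineString]]) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"alf_type": t},
            "geometry": mapping(line),
        }
        for t, lines in networks.items()
        for line in lines
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_lines_geojson(path) -> dict[str, list[LineString]]:
    gj = json.loads(Path(path).read_text())
    networks: dict[str, list[LineString]] = {}
    for feat in gj["features"]:
        networks.setdefault(feat["properties"]["alf_type"], []).append(
            shape(feat["geometry"])
        )
    return networks


def write_isopleths_geojson(path, isopleths: locoh_mod.IsoplethSet) -> None:
    features = []
    for level, poly in zip(isopleths.levels, isopleths.polygons):
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "level": level,
                    "area_m2": poly.area,
                    "perimeter_m": poly.length,
                },
                "geometry": mapping(poly),
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


# ---------------------------------------------------------------------------
# tracks: delimited text
# ---------------------------------------------------------------------------
def write_tracks_csv(path, tracks: list[Track]) -> None:
    frames = [
        pd.DataFrame(
            {
                "animal_id": t.animal_id,
                "species": t.species,
                "sex": t.sex,
                "timestamp": np.datetime_as_string(t.timestamps, unit="s"),
                "x": t.x,
                "y": t.y,
            }
        )
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("timestamp")
        tracks.append(
            Track(
                animal_id=str(animal_id),
                species=str(sub["species"].iloc[0]),
                sex=str(sub["sex"].iloc[0]),
                timestamps=sub["timestamp"].to_numpy(dtype="datetime64[s]"),
                x=sub["x"].to_numpy(float),
                y=sub["y"].to_numpy(float),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# line rasterization (all-touched)
# ---------------------------------------------------------------------------
def rasterize_lines(lines: list[LineString], grid: GridSpec) -> np.ndarray:
    """Binary raster: 1 where any line touches the cell's square extent.

    All-touched semantics — a 1-D line almost never covers a cell
    *center*, so presence is judged against the full cell square.
    """
    out = np.zeros(grid.shape, dtype=np.int8)
    for line in lines:
        minx, miny, maxx, maxy = line.bounds
        # pad the candidate window by one cell so lines running exactly
        # along a shared edge still test the cells on both sides
        c0 = max(int(np.floor((minx - grid.x0) / grid.cell)) - 1, 0)
        c1 = min(int(np.floor((maxx - grid.x0) / grid.cell)) + 1, grid.ncols - 1)
        r0 = max(int(np.floor((miny - grid.y0) / grid.cell)) - 1, 0)
        r1 = min(int(np.floor((maxy - grid.y0) / grid.cell)) + 1, grid.nrows - 1)
        if c1 < c0 or r1 < r0:
            continue
        rows, cols = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        rows, cols = rows.ravel(), cols.ravel()
        todo = out[rows, cols] == 0
        rows, cols = rows[todo], cols[todo]
        if len(rows) == 0:
            continue
        boxes = shapely.box(
            grid.x0 + cols * grid.cell,
            grid.y0 + rows * grid.cell,
            grid.x0 + (cols + 1) * grid.cell,
            grid.y0 + (rows + 1) * grid.cell,
        )
        hit = shapely.intersects(boxes, line)
        out[rows[hit], cols[hit]] = 1
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class PipelineConfig:
    grid: GridSpec
    output_dir: str
    synthetic: dict = field(default_factory=dict)
    locoh: dict = field(default_factory=dict)
    seasons: dict[str, int] = field(default_factory=lambda: dict(folds_mod.SEASON_MONTHS))
    models: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "grid" not in raw:
            raise ValueError("config is missing the template grid block")
        g = raw["grid"]
        grid = GridSpec(
            x0=float(g.get("x0", 0.0)),
            y0=float(g.get("y0", 0.0)),
            cell=float(g.get("cell", 30.0)),
            nrows=int(g["nrows"]),
            ncols=int(g["ncols"]),
            crs=str(g.get("crs", "EPSG:32612")),
        )
        return cls(
            grid=grid,
            output_dir=str(raw.get("output_dir", "alfrange_out")),
            synthetic=dict(raw.get("synthetic", {})),
            locoh=dict(raw.get("locoh", {})),
            seasons={k: int(v) for k, v in raw.get("seasons", folds_mod.SEASON_MONTHS).items()},
            models=dict(raw.get("models", {})),
            seed=int(raw.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------
def _simulate_inputs(cfg: PipelineConfig, seed: int):
    """Landscapes (per season), ALF networks/rasters, and tracks."""
    syn = cfg.synthetic
    rng = np.random.default_rng(seed)
    densities = {t: float(syn.get("densities", {}).get(t, 0.0)) for t in ALF_TYPES}
    networks = gen_alf_lines(
        cfg.grid, densities, syn.get("pattern", "random_segments"), seed=int(rng.integers(2**31))
    )
    alf_rasters = {t: rasterize_lines(networks[t], cfg.grid) for t in ALF_TYPES}

    bundles = {}
    for season, month in cfg.seasons.items():
        bundle = gen_landscape(cfg.grid, seed=int(rng.integers(2**31)), season_month=month)
        bundle.alf = alf_rasters
        bundle.alf_lines = networks
        bundles[season] = bundle

    n_animals = int(syn.get("n_animals", 4))
    n_fixes = int(syn.get("n_fixes", 150))
    # real tracking durations vary widely; draw each fold's length from a
    # range unless the config pins it
    fix_lo = int(syn.get("n_fixes_min", max(24, n_fixes // 2)))
    years = [int(y) for y in syn.get("years", [2021])]
    species = str(syn.get("species", "deer"))
    margin = 0.15
    tracks = []
    for a in range(n_animals):
        home = (
            rng.uniform(cfg.grid.x0 + margin * cfg.grid.width, cfg.grid.xmax - margin * cfg.grid.width),
            rng.uniform(cfg.grid.y0 + margin * cfg.grid.height, cfg.grid.ymax - margin * cfg.grid.height),
        )
        sex = "M" if a % 2 else "F"
        ts_parts, x_parts, y_parts = [], [], []
        for year in years:
            for season in sorted(cfg.seasons, key=cfg.seasons.get):
                params = MovementParams(
                    home_center=home,
                    attraction_rate=float(syn.get("attraction_rate", 0.15)),
                    step_scale=float(syn.get("step_scale", 250.0)),
                    habitat_beta={k: float(v) for k, v in syn.get("habitat_beta", {}).items()},
                    permeability={k: float(v) for k, v in syn.get("permeability", {}).items()},
                    season_month=cfg.seasons[season],
                    seed=int(rng.integers(2**31)),
                )
                n_i = int(rng.integers(fix_lo, n_fixes + 1)) if fix_lo < n_fixes else n_fixes
                t = simulate_track(
                    bundles[season], params, n_i,
                    animal_id=f"A{a:03d}", species=species, sex=sex, year=year,
                )
                ts_parts.append(t.timestamps)
                x_parts.append(t.x)
                y_parts.append(t.y)
        tracks.append(
            Track(
                animal_id=f"A{a:03d}", species=species, sex=sex,
                timestamps=np.concatenate(ts_parts),
                x=np.concatenate(x_parts),
                y=np.concatenate(y_parts),
            )
        )
    return bundles, networks, tracks


def run_pipeline(cfg: PipelineConfig, seed: int | None = None, write: bool = True) -> dict:
    """Execute the full chain and return the run report.

    Stages: input simulation (or track loading) -> folds -> k-LoCoH ODs
    -> shape metrics -> selection ratios -> hypothesis models ->
    prediction curves. Every stage writes its artifact under
    ``cfg.output_dir`` when ``write`` is true; the same config and seed
    reproduce byte-identical outputs.
    """
    seed = cfg.seed if seed is None else seed
    out = Path(cfg.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    tracks_path = cfg.synthetic.get("tracks_csv")
    bundles, networks, tracks = _simulate_inputs(cfg, seed)
    if tracks_path:
        tracks = read_tracks_csv(tracks_path)

    report: dict = {"seed": seed, "stages": {}}
    all_folds = folds_mod.split_folds(tracks, cfg.seasons)
    report["stages"]["folds"] = {"built": len(all_folds)}

    lc = locoh_mod.LocohConfig(
        k=cfg.locoh.get("k"),
        isopleth_levels=tuple(cfg.locoh.get("levels", locoh_mod.DEFAULT_LEVELS)),
    )
    extent = cfg.grid.extent_polygon()

    manifest_rows, metric_rows, selection_rows = [], [], []
    kept_folds = []
    ods = {}
    for fold in all_folds:
        decision = folds_mod.filter_fold(fold)
        if decision.kept:
            iso = locoh_mod.estimate_od(fold.points(), lc)
            od95 = iso.od95
            decision = folds_mod.filter_fold(
                fold,
                od_area_m2=od95.area,
                study_extent=extent,
                od_centroid=(od95.centroid.x, od95.centroid.y),
            )
        row = {
            "fold_id": fold.fold_id,
            "animal_id": fold.animal_id,
            "species": fold.species,
            "sex": fold.sex,
            "season": fold.season,
            "year": fold.year,
            "n_points": fold.n_points,
            "n_days": fold.n_days,
            "kept": decision.kept,
            "reason": decision.reason,
        }
        manifest_rows.append(row)
        if not decision.kept:
            continue
        kept_folds.append(fold)
        ods[fold.fold_id] = iso
        m = od_metrics.shape_metrics(iso.od95)
        metric_rows.append({"fold_id": fold.fold_id, **asdict(m)})
        bundle = bundles[fold.season]
        use = locoh_mod.od_intensity_raster(iso, cfg.grid)
        domain = selection_mod.availability_domain(fold.points(), iso.od95, cfg.grid)
        attrs = dict(bundle.attributes)
        attrs.update({t: bundle.alf[t].astype(float) for t in ALF_TYPES})
        for rec in selection_mod.selection_records(fold.fold_id, use, attrs, domain):
            selection_rows.append(asdict(rec))

    manifest = pd.DataFrame(manifest_rows)
    # weights are normalized within each species-season model dataset
    weights = {}
    for (_, _), group in _groupby_species_season(kept_folds):
        for f in folds_mod.fold_weight(group):
            weights[f.fold_id] = f.weight
    manifest["weight"] = manifest["fold_id"].map(weights)
    metrics = pd.DataFrame(metric_rows)
    selections = pd.DataFrame(selection_rows)
    selections = selections.rename(columns={"log_sr": "log_sr"})
    report["stages"]["filter"] = {
        "kept": int(manifest["kept"].sum()),
        "rejected": int((~manifest["kept"]).sum()),
    }

    fits = []
    coef_rows, curve_frames = [], []
    model_cfg = cfg.models
    requested = model_cfg.get("hypotheses", ["H1", "H2", "H3", "H4"])
    for (species, season), group in _groupby_species_season(kept_folds):
        try:
            table = build_dataset(manifest[manifest["kept"]], metrics, selections, species, season)
        except ValueError:
            continue
        for spec in _iter_specs(requested, table):
            try:
                fit = _fit_dropping_aliased(table, spec, report, species, season)
            except ValueError as err:
                report["stages"].setdefault("model_errors", []).append(
                    f"{spec.hypothesis}/{spec.response}/{species}-{season}: {err}"
                )
                continue
            if fit is None:
                continue
            fits.append((species, season, fit))
            for term, b, s in zip(fit.terms, fit.beta, fit.se):
                coef_rows.append(
                    {
                        "model": fit.spec.hypothesis,
                        "response": fit.spec.response,
                        "species": species,
                        "season": season,
                        "term": term,
                        "beta": b,
                        "se": s,
                        "used_random_effect": fit.used_random_effect,
                    }
                )
            focal = f"avail_{fit.spec.focal}" if fit.spec.focal else next(
                (t for t in fit.spec.fixed_terms if t.startswith("avail_")), None
            )
            if focal is None or focal not in fit.spec.fixed_terms:
                continue
            curve = predict_response_curve(fit, focal)
            curve.insert(0, "focal_term", focal)
            curve.insert(0, "response", fit.spec.response)
            curve.insert(0, "model", fit.spec.hypothesis)
            curve.insert(0, "species_season", f"{species}-{season}")
            curve_frames.append(curve)

    report["stages"]["models"] = {
        "fitted": len(fits),
        "lmm": sum(1 for *_, f in fits if f.used_random_effect),
        "lm_fallback": sum(1 for *_, f in fits if not f.used_random_effect),
    }

    if write:
        for season, bundle in bundles.items():
            for name, arr in bundle.attributes.items():
                write_ascii_raster(out / f"attr_{season}_{name}.asc", arr, cfg.grid)
        for t in ALF_TYPES:
            write_ascii_raster(out / f"alf_{t}.asc", next(iter(bundles.values())).alf[t], cfg.grid)
        write_lines_geojson(out / "alf_lines.geojson", networks)
        write_tracks_csv(out / "tracks.csv", tracks)
        manifest.to_csv(out / "fold_manifest.csv", index=False)
        metrics.to_csv(out / "shape_metrics.csv", index=False)
        selections.to_csv(out / "selection_records.csv", index=False)
        pd.DataFrame(coef_rows).to_csv(out / "coefficients.csv", index=False)
        if curve_frames:
            pd.concat(curve_frames, ignore_index=True).to_csv(out / "prediction_curves.csv", index=False)
        for fold_id, iso in ods.items():
            write_isopleths_geojson(out / f"isopleths_{fold_id}.geojson", iso)
        report["checksums"] = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            for p in sorted(out.glob("*.csv"))
        }
        (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _fit_dropping_aliased(table, spec, report, species, season):
    """Fit a hypothesis model, pruning aliased terms once if needed.

    Synthetic seasons can zero out a predictor entirely (July snow), so
    all-missing or collinear terms are dropped with a note rather than
    failing the whole run. A model whose focal term or response is
    degenerate is skipped.
    """
    import dataclasses

    from .models import RankDeficientDesign

    focal_term0 = f"avail_{spec.focal}" if spec.focal else None
    if table[spec.response].isna().all():
        report["stages"].setdefault("model_errors", []).append(
            f"{spec.hypothesis}/{spec.response}/{species}-{season}: response undefined"
        )
        return None
    all_nan = [
        t for t in spec.fixed_terms
        if any(table[part].isna().all() for part in t.split(":") if part in table)
    ]
    if all_nan:
        if focal_term0 in all_nan:
            report["stages"].setdefault("model_errors", []).append(
                f"{spec.hypothesis}/{spec.response}/{species}-{season}: focal term undefined"
            )
            return None
        report["stages"].setdefault("nan_dropped", []).append(
            f"{spec.hypothesis}/{spec.response}/{species}-{season}: {sorted(all_nan)}"
        )
        spec = dataclasses.replace(
            spec, fixed_terms=tuple(t for t in spec.fixed_terms if t not in all_nan)
        )
    try:
        return fit_model(table, spec)
    except RankDeficientDesign as err:
        focal_term = f"avail_{spec.focal}" if spec.focal else None
        if focal_term in err.aliased or spec.response in err.aliased:
            report["stages"].setdefault("model_errors", []).append(
                f"{spec.hypothesis}/{spec.response}/{species}-{season}: focal term aliased"
            )
            return None
        reduced = tuple(
            t for t in spec.fixed_terms
            if t not in err.aliased
            and not any(part in err.aliased for part in t.split(":"))
        )
        report["stages"].setdefault("aliased_dropped", []).append(
            f"{spec.hypothesis}/{spec.response}/{species}-{season}: {sorted(err.aliased)}"
        )
        return fit_model(table, dataclasses.replace(spec, fixed_terms=reduced))


def _groupby_species_season(folds):
    groups: dict[tuple[str, str], list] = {}
    for f in folds:
        groups.setdefault((f.species, f.season), []).append(f)
    return sorted(groups.items())


def _iter_specs(requested, table):
    from .models import ENV_ATTRIBUTES

    n = len(table)
    for h in requested:
        if h in ("H1", "H2"):
            spec = model_spec(h)
            if n >= len(spec.fixed_terms) + 3:
                yield spec
        elif h == "H3":
            for t in ALF_TYPES:
                spec = model_spec("H3", t)
                if n >= len(spec.fixed_terms) + 3:
                    yield spec
        elif h == "H4":
            for a in ENV_ATTRIBUTES:
                spec = model_spec("H4", a)
                if n >= len(spec.fixed_terms) + 3:
                    yield spec
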