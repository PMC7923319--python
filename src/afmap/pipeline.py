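"""End-to-end pipeline: simulate -> cohort -> rates -> scan -> bym -> report.

A single YAML-backed configuration drives every stage; all randomness flows
from one root seed through named per-stage substreams, so stages are
reproducible whether run together or separately.  Every stage writes
deterministically named artifacts and the run ends with a JSON manifest of
paths, SHA-256 hashes and the seeds used.
"""

from __future__ import annotations

import copy
import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._time import age_group_at
from .bym import McmcSettings, ModelSpec, fit_bym, fit_iid_only, residual_irr_table, sensitivity_analysis
from .cohort import build_cohort, longest_address
from .geography import Geography
from .rates import rate_ratio, wald_test_irr_change, yearly_rate_series, incidence_rate
from .reporting import summarize_cohort
from .scan import ScanWindowSpec, clusters_to_frame, clusters_to_geojson, stratified_scan
from .synthetic import SimulationParams, generate_geography, read_registry, simulate_cohort, write_registry

__all__ = ["default_config", "load_config", "run_pipeline"]

log = logging.getLogger("afmap")

_STAGES = ("simulate", "cohort", "rates", "scan", "bym", "report")


def default_config() -> dict:
    """The demo configuration: a 7x14 lattice standing in for 98 regions."""
    return {
        "seed": 0,
        "out": "afmap_run",
        "simulate": {
            "n_rows": 7,
            "n_cols": 14,
            "cell_km": 10.0,
            "n_persons": 20_000,
            "window": ["2006-01-01", "2015-12-31"],
        },
        "analysis": {"window": ["2011-01-01", "2015-12-31"]},
        "rates": {"enabled": True, "stratify_by": "income_q"},
        "scan": {
            "enabled": True,
            "presets": ["frac10"],
            "n_reps": 999,
            "alpha": 0.05,
            "max_points": 4_000,
        },
        "bym": {
            "enabled": True,
            "adjust": ["semi", "full"],
            "n_iter": 2_000,
            "n_burnin": 1_000,
            "thin": 2,
            "n_chains": 2,
            "sensitivity": False,
        },
    }


def load_config(path: str | Path | None) -> dict:
    """Default configuration overlaid with the YAML file (if given)."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _window(pair) -> tuple[dt.date, dt.date]:
    return (dt.date.fromisoformat(str(pair[0])), dt.date.fromisoformat(str(pair[1])))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2^31."""
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def _scan_points(persons, followups, window, max_points, seed) -> pd.DataFrame:
    """Case/non-case points at the longest-lived address, age at exit.

    When the cohort exceeds ``max_points``, all cases are kept and controls
    are down-sampled (seeded), keeping the Bernoulli scan tractable.
    """
    by_id = {p.person_id: p for p in persons}
    rows = []
    for pid, fu in followups.items():
        person = by_id[pid]
        rid, (x, y) = longest_address(person.address_periods, window)
        rows.append(
            {
                "person_id": pid,
                "x_km": x,
                "y_km": y,
                "is_case": fu.is_case,
                "age_group": age_group_at(person.birth_date, fu.exit_date),
                "region_id": rid,
            }
        )
    df = pd.DataFrame(rows)
    if len(df) > max_points:
        rng = np.random.default_rng(seed)
        cases = df[df["is_case"]]
        controls = df[~df["is_case"]]
        n_ctrl = max_points - len(cases)
        if n_ctrl < 1:
            raise ValueError("max_points leaves no room for controls")
        keep = rng.choice(len(controls), size=n_ctrl, replace=False)
        df = pd.concat([cases, controls.iloc[np.sort(keep)]], ignore_index=True)
    return df


def run_pipeline(config: dict, stages: tuple[str, ...] = _STAGES) -> dict:
    """Run the configured stages and return the manifest (also written out)."""
    cfg = copy.deepcopy(config)
    outdir = Path(cfg["out"])
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg["seed"])
    manifest: dict = {
        "version": __version__,
        "seed": root_seed,
        "stage_seeds": {},
        "artifacts": {},
        "config": cfg,
    }

    def register(stage: str, name: str, path: Path):
        manifest["artifacts"].setdefault(stage, {})[name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    sim_cfg = cfg["simulate"]
    geography = generate_geography(
        sim_cfg["n_rows"], sim_cfg["n_cols"], sim_cfg["cell_km"], root_seed
    )

    # ---- simulate ------------------------------------------------------
    registry_dir = outdir / "registry"
    if "simulate" in stages:
        seed = _stage_seed(root_seed, "simulate")
        manifest["stage_seeds"]["simulate"] = seed
        log.info("simulate: %d persons on %d regions", sim_cfg["n_persons"], geography.n_regions)
        params = SimulationParams(
            n_persons=int(sim_cfg["n_persons"]),
            study_window=_window(sim_cfg["window"]),
            seed=seed,
        )
        persons = simulate_cohort(params, geography)
        paths = write_registry(persons, registry_dir)
        geography.write(outdir / "geography.geojson", outdir / "adjacency.json")
        for name, p in paths.items():
            register("simulate", name, p)
        register("simulate", "geography", outdir / "geography.geojson")
        register("simulate", "adjacency", outdir / "adjacency.json")
    else:
        persons = read_registry(registry_dir)

    window = _window(cfg["analysis"]["window"])

    # ---- cohort --------------------------------------------------------
    cells_path = outdir / "person_time_cells.csv"
    if "cohort" in stages:
        log.info("cohort: building follow-up and person-time cells")
        cohort = build_cohort(persons, window)
        cohort.cells.to_csv(cells_path, index=False)
        register("cohort", "cells", cells_path)
    else:
        cohort = build_cohort(persons, window)

    # ---- rates ---------------------------------------------------------
    if "rates" in stages and cfg["rates"].get("enabled", True):
        log.info("rates: yearly series stratified by %s", cfg["rates"]["stratify_by"])
        series = yearly_rate_series(cohort.cells, cfg["rates"]["stratify_by"])
        rates_path = outdir / "yearly_rates.csv"
        series.to_csv(rates_path, index=False)
        register("rates", "series", rates_path)

        summary = {}
        years = sorted(series["year"].unique())
        lo_hi = {}
        for year in (years[0], years[-1]):
            sub = series[series["year"] == year].set_index("stratum")
            if "1" in sub.index and "5" in sub.index:
                a = incidence_rate(int(sub.loc["1", "cases"]), float(sub.loc["1", "person_years"]))
                b = incidence_rate(int(sub.loc["5", "cases"]), float(sub.loc["5", "person_years"]))
                lo_hi[year] = rate_ratio(a, b)
        if len(lo_hi) == 2:
            first, last = (lo_hi[y] for y in (years[0], years[-1]))
            summary = {
                "first_year": years[0],
                "last_year": years[-1],
                "irr_first": first.irr,
                "irr_last": last.irr,
                "wald_p_change": wald_test_irr_change(first, last),
            }
        summary_path = outdir / "rates_summary.json"
        _write_json(summary_path, summary)
        register("rates", "summary", summary_path)

    # ---- scan ----------------------------------------------------------
    if "scan" in stages and cfg["scan"].get("enabled", True):
        seed = _stage_seed(root_seed, "scan")
        manifest["stage_seeds"]["scan"] = seed
        points = _scan_points(
            persons, cohort.followups, window, int(cfg["scan"]["max_points"]), seed
        )
        for preset in cfg["scan"]["presets"]:
            log.info("scan: preset %s on %d points", preset, len(points))
            spec = ScanWindowSpec.preset(preset)
            results = stratified_scan(
                points,
                spec,
                n_reps=int(cfg["scan"]["n_reps"]),
                seed=_stage_seed(root_seed, f"scan:{preset}"),
                alpha=float(cfg["scan"]["alpha"]),
            )
            frames = []
            all_clusters = []
            for stratum, clusters in results.items():
                f = clusters_to_frame(clusters)
                f.insert(0, "age_group", stratum)
                frames.append(f)
                all_clusters.extend(clusters)
            table = (
                pd.concat(frames, ignore_index=True)
                if frames
                else clusters_to_frame([])
            )
            csv_path = outdir / f"scan_clusters_{preset}.csv"
            table.to_csv(csv_path, index=False)
            register("scan", f"clusters_{preset}", csv_path)
            gj_path = outdir / f"scan_clusters_{preset}.geojson"
            _write_json(gj_path, clusters_to_geojson(all_clusters))
            register("scan", f"circles_{preset}", gj_path)

    # ---- bym -----------------------------------------------------------
    if "bym" in stages and cfg["bym"].get("enabled", True):
        bym_cfg = cfg["bym"]
        adjust_effects = {
            "semi": ("age_group", "sex"),
            "full": ("age_group", "sex", "income", "education", "cohabitation"),
        }
        for adjust in bym_cfg["adjust"]:
            seed = _stage_seed(root_seed, f"bym:{adjust}")
            manifest["stage_seeds"][f"bym:{adjust}"] = seed
            log.info("bym: %s-adjusted fit", adjust)
            spec = ModelSpec(geography=geography, fixed_effects=adjust_effects[adjust])
            settings = McmcSettings(
                n_iter=int(bym_cfg["n_iter"]),
                n_burnin=int(bym_cfg["n_burnin"]),
                thin=int(bym_cfg["thin"]),
                n_chains=int(bym_cfg["n_chains"]),
                seed=seed,
            )
            fit = fit_bym(cohort.cells, spec, settings)
            fit_iid = fit_iid_only(cohort.cells, spec, settings)
            irr = residual_irr_table(fit)
            irr_path = outdir / f"residual_irr_{adjust}.csv"
            irr.to_csv(irr_path, index=False)
            register("bym", f"residual_irr_{adjust}", irr_path)

            choropleth = _irr_geojson(geography, irr)
            gj_path = outdir / f"residual_irr_{adjust}.geojson"
            _write_json(gj_path, choropleth)
            register("bym", f"choropleth_{adjust}", gj_path)

            summary = {
                "adjustment": adjust,
                "dic_bym": fit.dic,
                "dic_iid_only": fit_iid.dic,
                "p_d_bym": fit.p_d,
                "spatial_fraction": fit.spatial_fraction,
                "max_residual_irr": float(irr["irr_mean"].max()),
                "n_significant_regions": int(irr["significant"].sum()),
                "rhat_max": float(np.nanmax(list(fit.rhat.values()))),
                "converged": fit.converged,
                "beta": fit.beta_summary().to_dict(orient="index"),
            }
            sum_path = outdir / f"bym_summary_{adjust}.json"
            _write_json(sum_path, summary)
            register("bym", f"summary_{adjust}", sum_path)

            if bym_cfg.get("sensitivity") and adjust == "full":
                sens = sensitivity_analysis(cohort.cells, spec, settings)
                sens_path = outdir / "bym_sensitivity.csv"
                sens.to_csv(sens_path, index=False)
                register("bym", "sensitivity", sens_path)

    # ---- report --------------------------------------------------------
    if "report" in stages:
        table1 = summarize_cohort(cohort)
        t1_path = outdir / "cohort_characteristics.csv"
        table1.to_csv(t1_path, index=False)
        register("report", "characteristics", t1_path)

    manifest_path = outdir / "manifest.json"
    _write_json(manifest_path, manifest)
    return manifest


def _irr_geojson(geography: Geography, irr: pd.DataFrame) -> dict:
    """Residual-IRR map as GeoJSON; non-significant regions flagged for
    grey shading by the renderer."""
    by_region = irr.set_index("region_id")
    features = []
    for rid in geography.region_ids:
        x, y = geography.coords[rid]
        row = by_region.loc[rid]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {
                    "region_id": rid,
                    "irr": float(row["irr_mean"]),
                    "ci_low": float(row["ci_low"]),
                    "ci_high": float(row["ci_high"]),
                    "significant": bool(row["significant"]),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
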