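"""End-to-end orchestration of the analysis stages.

simulate -> calibrate/filter/bin/CKDE -> exposure draws -> regional
probability-forest ensembles -> aggregated reports, all reproducible
from a single seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import forest, radiocarbon, reporting
from .config import PipelineConfig
from .exposures import (
    ClimateGridSet,
    EventSeries,
    SSTSeries,
    build_exposures,
    draw_means,
    exposures_to_frame,
)
from .radiocarbon import PopulationKDE
from .synthetic import (
    dates_from_frame,
    generate_world,
    individuals_from_frame,
    save_world,
)

log = logging.getLogger("paleopeace")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def summarize_dataset(individuals: pd.DataFrame) -> dict:
    """Counts report: totals, per-region trauma counts and prevalences.

    Prevalence percentages are rounded to one decimal; an empty table
    reports prevalence as None (undefined).
    """

    def prevalence(n_trauma: int, n_total: int):
        if n_total == 0:
            return None
        return round(100.0 * n_trauma / n_total, 1)

    total = len(individuals)
    n_trauma = int(individuals["trauma"].sum()) if total else 0
    report = {
        "total_individuals": total,
        "trauma": n_trauma,
        "no_trauma": total - n_trauma,
        "prevalence_pct": prevalence(n_trauma, total),
        "n_sites": int(individuals["site_id"].nunique()) if total else 0,
        "regions": {},
    }
    if total:
        for region, grp in individuals.groupby("region", sort=True):
            t = int(grp["trauma"].sum())
            report["regions"][region] = {
                "total": len(grp),
                "trauma": t,
                "no_trauma": len(grp) - t,
                "prevalence_pct": prevalence(t, len(grp)),
            }
    report["n_regions"] = len(report["regions"])
    return report


def build_population_kdes(
    dates: list[radiocarbon.RadiocarbonDate],
    curves: dict[str, radiocarbon.CalibrationCurve],
    grid: np.ndarray,
    n_replicates: int,
    bandwidth: float,
    max_error: float,
    bin_cutoff: float,
    rng: np.random.Generator,
    taphonomic: bool = False,
) -> dict[str, list[PopulationKDE]]:
    """Filter, calibrate, bin and bootstrap per-region population curves."""
    kept, n_dropped = radiocarbon.filter_dates(dates, max_error=max_error)
    log.info("date filter: kept %d, dropped %d (error > %s)", len(kept), n_dropped, max_error)
    densities = {}
    for d in kept:
        curve = curves["marine" if d.material == "marine" else "terrestrial"]
        densities[d.lab_id] = radiocarbon.calibrate(d, curve)
    out: dict[str, list[PopulationKDE]] = {}
    for region in sorted({d.region for d in kept}):
        region_dates = [d for d in kept if d.region == region]
        bins = []
        for site in sorted({d.site_id for d in region_dates}):
            site_bins = radiocarbon.bin_dates(
                [d for d in region_dates if d.site_id == site], cutoff=bin_cutoff
            )
            bins.extend(radiocarbon.attach_densities(site_bins, densities))
        kdes = radiocarbon.build_ckde(
            bins, grid, n_replicates=n_replicates, bandwidth=bandwidth, rng=rng
        )
        if taphonomic:
            kdes = [radiocarbon.taphonomic_correct(k) for k in kdes]
        out[region] = kdes
    return out


def _load_inputs(config: PipelineConfig):
    individuals = individuals_from_frame(pd.read_csv(config.individuals_path))
    dates = dates_from_frame(pd.read_csv(config.dates_path))
    climate = ClimateGridSet.from_frame(pd.read_csv(config.climate_path))
    cores = []
    for p in config.sst_paths:
        df = pd.read_csv(p)
        name = Path(p).stem.removeprefix("sst_")
        lon = float(df["lon"].iloc[0]) if "lon" in df else np.nan
        lat = float(df["lat"].iloc[0]) if "lat" in df else np.nan
        cores.append(SSTSeries(name, lon, lat, df["century"].to_numpy(), df["sst"].to_numpy()))
    enso_df = pd.read_csv(config.enso_path)
    enso = EventSeries("enso", enso_df["century"].to_numpy(), enso_df["events"].to_numpy())
    return individuals, dates, climate, cores, enso


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a manifest of outputs and timings."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": timings}

    ss = np.random.SeedSequence(config.seed)
    seed_world, seed_kde, seed_expo, seed_coast, seed_inland = (
        int(s.generate_state(1)[0]) for s in ss.spawn(5)
    )

    t0 = time.perf_counter()
    try:
        if config.simulate:
            config.world.seed = seed_world
            world = generate_world(config.world)
            if config.save_inputs:
                save_world(world, out / "data")
            individuals, dates = world.individuals, world.dates
            climate, cores, enso = world.climate, world.sst_cores, world.enso
        else:
            individuals, dates, climate, cores, enso = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001 - stage context wrapper
        raise StageError("load", str(exc)) from exc
    timings["load_s"] = round(time.perf_counter() - t0, 3)

    ind_frame = pd.DataFrame(
        {
            "id": [i.id for i in individuals],
            "site_id": [i.site_id for i in individuals],
            "trauma": [i.trauma for i in individuals],
            "region": [i.region for i in individuals],
        }
    )
    summary = summarize_dataset(ind_frame)
    (out / "dataset_summary.json").write_text(json.dumps(summary, indent=2))

    t0 = time.perf_counter()
    try:
        if config.curve_path:
            terrestrial = radiocarbon.read_curve(config.curve_path)
        else:
            terrestrial = radiocarbon.load_reference_curve()
        marine = (
            radiocarbon.read_curve(config.marine_curve_path)
            if config.marine_curve_path
            else terrestrial
        )
        kdes = build_population_kdes(
            dates,
            {"terrestrial": terrestrial, "marine": marine},
            grid=climate.centuries,
            n_replicates=config.kde_replicates,
            bandwidth=config.kde_bandwidth,
            max_error=config.max_date_error,
            bin_cutoff=config.bin_cutoff,
            rng=np.random.default_rng(seed_kde),
            taphonomic=config.taphonomic_correction,
        )
        rows = [
            {"region": region, "replicate_id": k.replicate_id, "cal_bp": y, "density": d}
            for region, ks in kdes.items()
            for k in ks
            for y, d in zip(k.cal_bp, k.density)
        ]
        pd.DataFrame(rows).to_csv(out / "population_kdes.csv", index=False)
    except Exception as exc:
        raise StageError("ckde", str(exc)) from exc
    timings["ckde_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    try:
        exposures = build_exposures(
            individuals,
            climate,
            cores,
            enso,
            kdes,
            n_draws=config.n_draws,
            radius_km=config.radius_km,
            rng=np.random.default_rng(seed_expo),
        )
        expo_table = exposures_to_frame(exposures)
        means = draw_means(exposures)
    except Exception as exc:
        raise StageError("exposures", str(exc)) from exc
    timings["exposures_s"] = round(time.perf_counter() - t0, 3)

    region_seeds = {"coast": seed_coast, "inland": seed_inland}
    for region in config.regions:
        t0 = time.perf_counter()
        try:
            ids = [i.id for i in individuals if i.region == region]
            if not ids:
                log.warning("region %s: no individuals, skipped", region)
                continue
            region_means = means.loc[means.index.isin(ids)]
            if region == "inland":
                region_means = region_means.drop(columns=["sst"], errors="ignore")
            retained, corr = forest.screen_collinearity(
                region_means.reset_index(),
                threshold=config.model.collinearity_threshold,
            )
            region_table = expo_table[expo_table["individual_id"].isin(ids)]
            if region == "inland":
                region_table = region_table.drop(columns=["sst"], errors="ignore")
            model_cfg = forest.ModelConfig(**{**config.model.__dict__, "seed": region_seeds[region]})
            runs = forest.run_ensemble(
                region_table, ind_frame, model_cfg, region=region, retained=retained
            )
            frames = forest.runs_to_frames(runs)
            for name, df in frames.items():
                df.to_csv(out / f"{name}_{region}.csv", index=False)
            agg = reporting.aggregate(runs)
            agg.correlation = reporting.correlation_matrix(region_means)
            reporting.write_summary(agg, out)
        except Exception as exc:
            raise StageError(f"ensemble:{region}", str(exc)) from exc
        timings[f"ensemble_{region}_s"] = round(time.perf_counter() - t0, 3)

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
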